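"""Cu(II) coordination geometry: distances, axial/equatorial roles,
denticity and hydrogen-bond contacts.

The LPMO copper is held by the histidine brace — the N-terminal
(methylated) histidine donating its amino nitrogen and imidazole nitrogen
plus a second histidine imidazole — with a tyrosine oxygen and one
exchangeable equatorial and one axial position completing a distorted
tetragonal bipyramid. This module measures that arrangement in a labeled
:class:`SiteModel` and classifies ligand binding modes.

Donor roles use the field's labels: ``N_im(Me-His1)``, ``N_am(Me-His1)``,
``N_im(His83)``, ``O(Tyr166)``, ``L_eq``, ``L_ax``. pi-coordinated groups
(e.g. a phenyl ring) are represented by explicitly tagged ring carbons and
reported as the mean Cu–carbon distance.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

#: Donor roles in conventional table order.
ROLE_ORDER = (
    "N_im(Me-His1)",
    "N_am(Me-His1)",
    "N_im(His83)",
    "O(Tyr166)",
    "L_eq",
    "L_ax",
)

#: The three nitrogen donors defining the equatorial plane.
N_DONORS = ("N_im(Me-His1)", "N_am(Me-His1)", "N_im(His83)")

#: Cu–donor distance (Angstrom) below which a donor counts as bound.
DEFAULT_BOND_CUTOFF = 2.6

#: Default H...acceptor distance for hydrogen-bond contacts, Angstrom.
DEFAULT_HBOND_MAX = 2.2


@dataclass
class PolarHydrogen:
    label: str
    coord: np.ndarray
    partner_label: str  # covalently bound heavy atom, excluded as acceptor


@dataclass
class Acceptor:
    label: str
    element: str  # O or N
    coord: np.ndarray


@dataclass
class LigandAtom:
    label: str
    element: str
    coord: np.ndarray
    is_donor: bool = False


@dataclass
class SiteModel:
    """Labeled copper site: Cu, donor atoms by role, optional extras.

    ``donors`` maps a role to either a single coordinate or, for
    pi-coordination, an (n, 3) array of tagged ring-carbon coordinates.
    """

    cu: np.ndarray
    donors: dict[str, np.ndarray] = field(default_factory=dict)
    ligand_atoms: list[LigandAtom] = field(default_factory=list)
    hydrogens: list[PolarHydrogen] = field(default_factory=list)
    acceptors: list[Acceptor] = field(default_factory=list)
    intended_roles: dict[str, str] = field(default_factory=dict)  # role -> axial|equatorial

    def __post_init__(self) -> None:
        self.cu = np.asarray(self.cu, dtype=float)
        if self.cu.shape != (3,):
            raise ValueError("exactly one Cu position of shape (3,) is required")
        clean = {}
        for role, xyz in self.donors.items():
            arr = np.asarray(xyz, dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"non-finite coordinates for donor {role!r}")
            clean[role] = arr
        self.donors = clean


@dataclass
class CoordinationRow:
    """One Table-style row: six Cu–donor distances with flags."""

    distances: dict[str, float | None]
    ring_average: set[str]
    not_occupied: set[str]
    denticity_count: int | None = None
    denticity_label: str | None = None

    def as_tuple(self) -> tuple[float | None, ...]:
        return tuple(self.distances[r] for r in ROLE_ORDER)


def _dist(a: np.ndarray, b: np.ndarray) -> float:
    return float(np.linalg.norm(np.asarray(a, float) - np.asarray(b, float)))


def cu_distances(site: SiteModel) -> CoordinationRow:
    """Euclidean Cu–donor distances in table order.

    Missing roles are flagged as unoccupied rather than raising;
    pi-coordinated roles (ring-carbon arrays) report the mean distance to
    the tagged ring carbons and are flagged.
    """
    distances: dict[str, float | None] = {}
    ring_average: set[str] = set()
    not_occupied: set[str] = set()
    for role in ROLE_ORDER:
        if role not in site.donors:
            distances[role] = None
            not_occupied.add(role)
            continue
        xyz = site.donors[role]
        if xyz.ndim == 2:
            distances[role] = float(
                np.mean(np.linalg.norm(xyz - site.cu, axis=1))
            )
            ring_average.add(role)
        else:
            distances[role] = _dist(site.cu, xyz)
    return CoordinationRow(
        distances=distances, ring_average=ring_average, not_occupied=not_occupied
    )


def _donor_point(xyz: np.ndarray) -> np.ndarray:
    return xyz.mean(axis=0) if xyz.ndim == 2 else xyz


def classify_axial_equatorial(
    site: SiteModel, threshold_deg: float = 45.0
) -> dict[str, tuple[str, float]]:
    """Axial/equatorial assignment of non-brace donors.

    The equatorial plane is defined by the three nitrogen donors; its
    normal is anchored at the Cu. A donor whose Cu->donor vector makes an
    angle of more than ``threshold_deg`` with the plane is axial, otherwise
    equatorial (ties at the threshold go to equatorial). Returns
    ``role -> (assignment, angle_to_plane_deg)``.
    """
    for role in N_DONORS:
        if role not in site.donors:
            raise ValueError(f"nitrogen donor {role!r} required to define the plane")
    n1, n2, n3 = (_donor_point(site.donors[r]) for r in N_DONORS)
    normal = np.cross(n2 - n1, n3 - n1)
    norm = np.linalg.norm(normal)
    if norm < 1e-9 * max(np.linalg.norm(n2 - n1), np.linalg.norm(n3 - n1), 1.0):
        raise ValueError("the three nitrogen donors are collinear")
    normal /= norm

    out: dict[str, tuple[str, float]] = {}
    for role, xyz in site.donors.items():
        if role in N_DONORS:
            continue
        v = _donor_point(xyz) - site.cu
        nv = np.linalg.norm(v)
        if nv == 0:
            raise ValueError(f"donor {role!r} coincides with the Cu")
        sin_angle = abs(float(np.dot(v / nv, normal)))
        angle = float(np.degrees(np.arcsin(np.clip(sin_angle, 0.0, 1.0))))
        # ties at the threshold go to equatorial; the epsilon absorbs
        # floating-point noise for donors placed exactly on the boundary
        assignment = "axial" if angle > threshold_deg + 1e-9 else "equatorial"
        out[role] = (assignment, angle)
    return out


def denticity(
    site: SiteModel, bond_cutoff: float = DEFAULT_BOND_CUTOFF
) -> tuple[int, str]:
    """Number of ligand donor atoms bound to the Cu within ``bond_cutoff``.

    Returns the count and the conventional label (``unbound``,
    ``monodentate``, ``bidentate``, ``tridentate``).
    """
    count = sum(
        1
        for atom in site.ligand_atoms
        if atom.is_donor and _dist(site.cu, atom.coord) <= bond_cutoff
    )
    labels = {0: "unbound", 1: "monodentate", 2: "bidentate", 3: "tridentate"}
    return count, labels.get(count, f"{count}-dentate")


def hbond_contacts(
    site: SiteModel, d_max: float = DEFAULT_HBOND_MAX
) -> list[tuple[str, str, float]]:
    """Polar H ... O/N acceptor contacts with distance <= ``d_max``.

    Covalent partners are excluded by label; an empty list is a valid
    result. Sorted by distance.
    """
    contacts = []
    for h in site.hydrogens:
        for acc in site.acceptors:
            if acc.label == h.partner_label:
                continue
            if acc.element not in ("O", "N"):
                continue
            d = _dist(h.coord, acc.coord)
            if d <= d_max:
                contacts.append((h.label, acc.label, d))
    return sorted(contacts, key=lambda t: t[2])


def coordination_table(
    site: SiteModel, bond_cutoff: float = DEFAULT_BOND_CUTOFF
) -> CoordinationRow:
    """Distances plus denticity in one row."""
    row = cu_distances(site)
    row.denticity_count, row.denticity_label = denticity(site, bond_cutoff)
    return row


# ---------------------------------------------------------------------------
# PDB input


def load_site_from_pdb(pdb_path, role_map_path) -> SiteModel:
    """Build a SiteModel from a PDB file and a JSON role map.

    The map keys are ``"RESNAME RESSEQ ATOMNAME"`` strings; values are
    either a donor role from :data:`ROLE_ORDER`, ``"cu"`` for the copper,
    or ``"ligand_donor"``/``"ligand"`` for inhibitor atoms.
    """
    from Bio.PDB import PDBParser

    with open(role_map_path) as fh:
        role_map = json.load(fh)

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("site", pdb_path)

    cu = None
    donors: dict[str, np.ndarray] = {}
    ligand_atoms: list[LigandAtom] = []
    for atom in structure.get_atoms():
        res = atom.get_parent()
        key = f"{res.get_resname().strip()} {res.get_id()[1]} {atom.get_name().strip()}"
        if key not in role_map:
            continue
        role = role_map[key]
        coord = np.array(atom.get_coord(), dtype=float)
        if role == "cu":
            if cu is not None:
                raise ValueError("more than one atom mapped to the copper role")
            cu = coord
        elif role in ("ligand", "ligand_donor"):
            ligand_atoms.append(
                LigandAtom(
                    label=key,
                    element=atom.element or atom.get_name()[0],
                    coord=coord,
                    is_donor=(role == "ligand_donor"),
                )
            )
        else:
            donors[role] = coord
    if cu is None:
        raise ValueError("no atom mapped to the copper role")
    return SiteModel(cu=cu, donors=donors, ligand_atoms=ligand_atoms)
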