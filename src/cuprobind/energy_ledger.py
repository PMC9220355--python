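"""Assembly of ligand–Cu(II) binding (free) energies from species energies.

The supermolecular route computes the binding energy of a ligand L to the
active-site model A from total electronic energies of the complex AL in a
protein-like continuum (diethyl ether, DEE), the free site in DEE and the
free ligand in water, plus a Boys–Bernardi counterpoise estimate of the
basis set superposition error (BSSE)::

    dE_bind = E(AL, DEE) - E(A, DEE) - E(L, H2O) + dE_bsse

The same quantity decomposes exactly into physically interpretable steps —
interaction at the complex geometry, deformation of each partner into that
geometry, transfer of the ligand from water into the DEE continuum
(dehydration), and the BSSE term::

    dE_bind = dE_int + dE_def_A + dE_def_L + dE_dehydr_L + dE_bsse

Adding rigid-rotor/harmonic-oscillator thermal corrections gives the
binding free energy ``dG_bind = dE_bind + dG_bind_corr``.

Every energy entering these cycles is one :class:`EnergyRecord`; a set of
records is held in an :class:`EnergyTable` keyed by (species, geometry,
basis, solvent). The BSSE components are evaluated as printed source
formulas ``E_ghost - E_own`` (negative: extra basis functions lower the
monomer energy); ``bsse_sign="conventional"`` negates them for the usual
counterpoise direction in which the correction weakens the binding.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .units import convert_energy

SPECIES = ("AL", "A", "L")
GEOMETRIES = ("native", "complex")
BASES = ("own", "complex")
SOLVENTS = ("DEE", "water")

#: Default temperature for thermal corrections, K.
DEFAULT_TEMPERATURE = 298.15

#: Wildcard ligand id: one shared active-site block applying to all ligands.
SHARED = "*"


class MissingSlotError(KeyError):
    """A required (species, geometry, basis, solvent) record is absent."""


@dataclass(frozen=True)
class EnergyRecord:
    """Total electronic energy of one species in one context, kJ/mol."""

    ligand_id: str
    species: str
    geometry: str
    basis: str
    solvent: str
    energy: float

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}, got {self.species!r}")
        if self.geometry not in GEOMETRIES:
            raise ValueError(f"geometry must be one of {GEOMETRIES}")
        if self.basis not in BASES:
            raise ValueError(f"basis must be one of {BASES}")
        if self.solvent not in SOLVENTS:
            raise ValueError(f"solvent must be one of {SOLVENTS}")
        if not _finite(self.energy):
            raise ValueError(f"energy must be finite, got {self.energy}")


@dataclass(frozen=True)
class ThermalCorrection:
    """Thermal correction to the free energy of one species, kJ/mol."""

    ligand_id: str
    species: str
    g_corr: float

    def __post_init__(self) -> None:
        if self.species not in SPECIES:
            raise ValueError(f"species must be one of {SPECIES}")
        if not _finite(self.g_corr):
            raise ValueError("g_corr must be finite")


@dataclass
class BindingDecomposition:
    """Binding energy of one ligand and its additive contributions, kJ/mol."""

    ligand_id: str
    dE_int: float
    dE_def_A: float
    dE_def_L: float
    dE_dehydr_L: float
    dE_bsse_A: float
    dE_bsse_L: float
    dE_bsse: float
    dE_bind: float
    dG_bind_corr: float | None = None
    dG_bind: float | None = None


def _finite(x: float) -> bool:
    return x == x and abs(x) != float("inf")


# Canonical slot names -> (species, geometry, basis, solvent).
SLOTS: dict[str, tuple[str, str, str, str]] = {
    # complex in its optimized geometry, DEE continuum
    "E_AL": ("AL", "complex", "own", "DEE"),
    # relaxed monomers
    "E_A_native": ("A", "native", "own", "DEE"),
    "E_L_water": ("L", "native", "own", "water"),
    "E_L_dee": ("L", "native", "own", "DEE"),
    # monomers frozen at the complex geometry, own basis
    "E_A_complex": ("A", "complex", "own", "DEE"),
    "E_L_complex": ("L", "complex", "own", "DEE"),
    # monomers at the complex geometry with the full dimer (ghost) basis
    "E_A_ghost": ("A", "complex", "complex", "DEE"),
    "E_L_ghost": ("L", "complex", "complex", "DEE"),
}


class EnergyTable:
    """Lookup table of species energies, with an optional shared site block.

    Records with ``ligand_id == "*"`` describe the free active site and are
    consulted whenever a ligand has no record of its own for that slot.
    """

    def __init__(self, records: Iterable[EnergyRecord]):
        self._index: dict[tuple[str, str, str, str, str], float] = {}
        for rec in records:
            key = (rec.ligand_id, rec.species, rec.geometry, rec.basis, rec.solvent)
            if key in self._index:
                raise ValueError(f"duplicate energy record for {key}")
            self._index[key] = rec.energy

    def ligands(self) -> list[str]:
        ids = {k[0] for k in self._index if k[0] != SHARED}
        return sorted(ids)

    def lookup(self, ligand_id: str, slot: str) -> float:
        species, geometry, basis, solvent = SLOTS[slot]
        for lid in (ligand_id, SHARED):
            key = (lid, species, geometry, basis, solvent)
            if key in self._index:
                return self._index[key]
        raise MissingSlotError(
            f"ligand {ligand_id!r}: no energy record for slot {slot} "
            f"(species={species}, geometry={geometry}, basis={basis}, "
            f"solvent={solvent})"
        )


def bsse_correction(
    E_AL_A: float,
    E_A_A: float,
    E_AL_L: float,
    E_L_L: float,
    bsse_sign: str = "printed",
) -> tuple[float, float, float]:
    """Counterpoise BSSE components for the site (A) and the ligand (L).

    ``E_AL_A``/``E_AL_L`` are monomer energies evaluated with the full dimer
    basis (ghost functions on the partner), ``E_A_A``/``E_L_L`` with the
    monomer's own basis, all at the complex geometry.

    ``bsse_sign="printed"`` evaluates ``E_ghost - E_own`` (components are
    typically negative); ``"conventional"`` negates both components so that
    the correction counteracts the artificial overbinding.
    """
    if bsse_sign not in ("printed", "conventional"):
        raise ValueError("bsse_sign must be 'printed' or 'conventional'")
    d_a = E_AL_A - E_A_A
    d_l = E_AL_L - E_L_L
    if bsse_sign == "conventional":
        d_a, d_l = -d_a, -d_l
    return d_a, d_l, d_a + d_l


def _bsse_from_table(
    table: EnergyTable, ligand_id: str, bsse_sign: str
) -> tuple[float, float, float]:
    return bsse_correction(
        table.lookup(ligand_id, "E_A_ghost"),
        table.lookup(ligand_id, "E_A_complex"),
        table.lookup(ligand_id, "E_L_ghost"),
        table.lookup(ligand_id, "E_L_complex"),
        bsse_sign=bsse_sign,
    )


def binding_energy(
    table: EnergyTable, ligand_id: str, bsse_sign: str = "printed"
) -> float:
    """Direct supermolecular binding energy of one ligand, kJ/mol."""
    _, _, d_bsse = _bsse_from_table(table, ligand_id, bsse_sign)
    return (
        table.lookup(ligand_id, "E_AL")
        - table.lookup(ligand_id, "E_A_native")
        - table.lookup(ligand_id, "E_L_water")
        + d_bsse
    )


def binding_free_energy(
    dE_bind: float, g_corr_AL: float, g_corr_A: float, g_corr_L: float
) -> tuple[float, float]:
    """Thermal correction to binding and the resulting binding free energy."""
    for name, v in (("AL", g_corr_AL), ("A", g_corr_A), ("L", g_corr_L)):
        if v is None or not _finite(v):
            raise ValueError(f"thermal correction for species {name} missing or not finite")
    dG_corr = g_corr_AL - g_corr_A - g_corr_L
    return dG_corr, dE_bind + dG_corr


def decompose(
    table: EnergyTable,
    ligand_id: str,
    thermal: Mapping[tuple[str, str], float] | None = None,
    bsse_sign: str = "printed",
) -> BindingDecomposition:
    """Full additive decomposition of one ligand's binding energy.

    Parameters
    ----------
    table:
        Energy table containing every slot in :data:`SLOTS` for the ligand.
    thermal:
        Optional mapping ``(ligand_id, species) -> g_corr`` (kJ/mol). The
        shared id ``"*"`` is honoured for the free site. When absent, the
        ``dG`` fields stay ``None`` rather than being zero-filled.
    """
    e_al = table.lookup(ligand_id, "E_AL")
    e_a_native = table.lookup(ligand_id, "E_A_native")
    e_l_water = table.lookup(ligand_id, "E_L_water")
    e_l_dee = table.lookup(ligand_id, "E_L_dee")
    e_a_complex = table.lookup(ligand_id, "E_A_complex")
    e_l_complex = table.lookup(ligand_id, "E_L_complex")

    d_bsse_a, d_bsse_l, d_bsse = _bsse_from_table(table, ligand_id, bsse_sign)

    dE_int = e_al - e_a_complex - e_l_complex
    dE_def_A = e_a_complex - e_a_native
    dE_def_L = e_l_complex - e_l_dee
    dE_dehydr_L = e_l_dee - e_l_water
    dE_bind = dE_int + dE_def_A + dE_def_L + dE_dehydr_L + d_bsse

    decomp = BindingDecomposition(
        ligand_id=ligand_id,
        dE_int=dE_int,
        dE_def_A=dE_def_A,
        dE_def_L=dE_def_L,
        dE_dehydr_L=dE_dehydr_L,
        dE_bsse_A=d_bsse_a,
        dE_bsse_L=d_bsse_l,
        dE_bsse=d_bsse,
        dE_bind=dE_bind,
    )

    if thermal is not None:
        g = {}
        for sp in SPECIES:
            if (ligand_id, sp) in thermal:
                g[sp] = thermal[(ligand_id, sp)]
            elif (SHARED, sp) in thermal:
                g[sp] = thermal[(SHARED, sp)]
            else:
                raise MissingSlotError(
                    f"ligand {ligand_id!r}: missing thermal correction for species {sp}"
                )
        decomp.dG_bind_corr, decomp.dG_bind = binding_free_energy(
            dE_bind, g["AL"], g["A"], g["L"]
        )
    return decomp


def decompose_all(
    table: EnergyTable,
    thermal: Mapping[tuple[str, str], float] | None = None,
    bsse_sign: str = "printed",
) -> list[BindingDecomposition]:
    return [decompose(table, lid, thermal, bsse_sign) for lid in table.ligands()]


def rank_ligands(
    decomps: Sequence[BindingDecomposition], key: str = "dE_bind"
) -> list[BindingDecomposition]:
    """Order ligands by ascending (most negative first) binding energy.

    Ties are broken by ligand id so the ranking is reproducible.
    """
    if not decomps:
        raise ValueError("cannot rank an empty set of ligands")
    if key not in ("dE_bind", "dG_bind"):
        raise ValueError("key must be 'dE_bind' or 'dG_bind'")
    vals = []
    for d in decomps:
        v = getattr(d, key)
        if v is None:
            raise ValueError(f"ligand {d.ligand_id!r} has no {key}")
        vals.append(v)
    order = sorted(range(len(decomps)), key=lambda i: (vals[i], decomps[i].ligand_id))
    return [decomps[i] for i in order]


# ---------------------------------------------------------------------------
# CSV interfaces


def read_energies_csv(path) -> EnergyTable:
    """Read a long-format species-energy table.

    Columns: ligand_id, species, geometry, basis, solvent, energy, unit.
    Energies are converted to kJ/mol on ingest; ``unit`` may vary per row.
    """
    df = pd.read_csv(path)
    required = {"ligand_id", "species", "geometry", "basis", "solvent", "energy"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"energies table is missing columns {sorted(missing)}")
    units = df["unit"] if "unit" in df.columns else pd.Series(["hartree"] * len(df))
    records = [
        EnergyRecord(
            ligand_id=str(row.ligand_id),
            species=str(row.species),
            geometry=str(row.geometry),
            basis=str(row.basis),
            solvent=str(row.solvent),
            energy=convert_energy(float(row.energy), str(unit)),
        )
        for row, unit in zip(df.itertuples(index=False), units)
    ]
    return EnergyTable(records)


def read_thermal_csv(path) -> dict[tuple[str, str], float]:
    """Read thermal corrections: ligand_id, species, g_corr[, unit]."""
    df = pd.read_csv(path)
    required = {"ligand_id", "species", "g_corr"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"thermal table is missing columns {sorted(missing)}")
    units = df["unit"] if "unit" in df.columns else pd.Series(["kJ/mol"] * len(df))
    out: dict[tuple[str, str], float] = {}
    for row, unit in zip(df.itertuples(index=False), units):
        key = (str(row.ligand_id), str(row.species))
        if key in out:
            raise ValueError(f"duplicate thermal correction for {key}")
        out[key] = convert_energy(float(row.g_corr), str(unit))
    return out


def decompositions_to_frame(decomps: Sequence[BindingDecomposition]) -> pd.DataFrame:
    """One row per ligand with every component, for CSV export or plotting."""
    cols = [
        "ligand_id", "dE_int", "dE_def_A", "dE_def_L", "dE_dehydr_L",
        "dE_bsse_A", "dE_bsse_L", "dE_bsse", "dE_bind", "dG_bind_corr", "dG_bind",
    ]
    rows = [{c: getattr(d, c) for c in cols} for d in decomps]
    return pd.DataFrame(rows, columns=cols)
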