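"""Copper-site hydration analysis and trajectory clustering.

The water structure around the catalytic Cu is summarised with the radial
distribution function g(r): the density of water oxygens at distance r
from the copper, relative to the bulk density. Hydration-shell occupancies
follow by integrating 4*pi*rho*g(r)*r^2 between shell boundaries.
Conformational heterogeneity is summarised with a GROMOS-style greedy
RMSD-cutoff clustering of trajectory frames after optimal least-squares
superposition.

Frames live in plain arrays with per-atom role tags ("copper",
"water_oxygen", ...); boxes are orthorhombic or absent (non-periodic
fixtures supply the bulk density explicitly).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import argrelextrema, find_peaks

ROLE_COPPER = "copper"
ROLE_WATER_O = "water_oxygen"


@dataclass
class Frame:
    """One trajectory frame: coordinates plus per-atom element/role tags."""

    coords: np.ndarray  # (N, 3) Angstrom
    elements: np.ndarray  # (N,) str
    roles: np.ndarray  # (N,) str
    box: np.ndarray | None = None  # (3,) orthorhombic lengths, Angstrom

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        self.elements = np.asarray(self.elements, dtype=object)
        self.roles = np.asarray(self.roles, dtype=object)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must have shape (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("coordinates must be finite")
        if self.box is not None:
            self.box = np.asarray(self.box, dtype=float)
            if self.box.shape != (3,):
                raise ValueError(
                    "box must be three orthorhombic lengths; "
                    "triclinic boxes are not supported"
                )
            if np.any(self.box <= 0):
                raise ValueError("box lengths must be positive")

    def select(self, role: str) -> np.ndarray:
        return np.flatnonzero(self.roles == role)


@dataclass
class RDFProfile:
    r: np.ndarray  # bin centers, Angstrom
    g: np.ndarray
    rho: float  # bulk density, waters per A^3
    n_frames: int
    dr: float
    description: str = ""


@dataclass
class ShellReport:
    peak1: float | None
    min1: float | None
    peak2: float | None
    min2: float | None
    coordination1: float | None
    coordination2: float | None
    flags: list[str] = field(default_factory=list)


@dataclass
class SuperpositionResult:
    rmsd: float
    rotation: np.ndarray  # (3, 3), proper
    translation: np.ndarray  # (3,)


@dataclass
class ClusterAssignment:
    labels: np.ndarray  # frame index -> cluster id
    centroids: list[int]  # cluster id -> centroid frame index
    members: list[list[int]]  # cluster id -> member frame indices
    cutoff: float


def _minimum_image(delta: np.ndarray, box: np.ndarray | None) -> np.ndarray:
    if box is None:
        return delta
    return delta - box * np.round(delta / box)


def radial_distribution(
    frames: list[Frame],
    ref_role: str = ROLE_COPPER,
    target_role: str = ROLE_WATER_O,
    dr: float = 0.02,
    r_max: float = 8.0,
    rho: float | None = None,
) -> RDFProfile:
    """Radial distribution of target atoms around a single reference atom.

    Distances use the minimum-image convention for periodic frames. The
    histogram is normalised per frame by the spherical-shell volume
    ``4 pi r^2 dr`` and the bulk density ``rho = N_target / V_box``
    (supplied explicitly for non-periodic input).
    """
    if not frames:
        raise ValueError("no frames supplied")
    edges = np.arange(0.0, r_max + dr, dr)
    counts = np.zeros(len(edges) - 1)
    rho_sum = 0.0
    n_periodic = 0
    for frame in frames:
        ref_idx = frame.select(ref_role)
        if len(ref_idx) != 1:
            raise ValueError(
                f"reference role {ref_role!r} resolves to {len(ref_idx)} atoms, "
                "expected exactly one"
            )
        tgt_idx = frame.select(target_role)
        if len(tgt_idx) == 0:
            raise ValueError(f"no atoms with target role {target_role!r}")
        if frame.box is not None:
            if r_max > frame.box.min() / 2.0:
                raise ValueError(
                    f"r_max {r_max} exceeds half the smallest box length "
                    f"{frame.box.min() / 2.0}"
                )
            rho_sum += len(tgt_idx) / float(np.prod(frame.box))
            n_periodic += 1
        delta = _minimum_image(
            frame.coords[tgt_idx] - frame.coords[ref_idx[0]], frame.box
        )
        dist = np.linalg.norm(delta, axis=1)
        counts += np.histogram(dist, bins=edges)[0]

    if rho is None:
        if n_periodic == 0:
            raise ValueError(
                "bulk density rho must be supplied for non-periodic frames"
            )
        rho = rho_sum / n_periodic

    centers = 0.5 * (edges[:-1] + edges[1:])
    shell_vol = 4.0 * np.pi * centers**2 * dr
    g = counts / (len(frames) * shell_vol * rho)
    return RDFProfile(
        r=centers,
        g=g,
        rho=float(rho),
        n_frames=len(frames),
        dr=dr,
        description=f"{ref_role} -> {target_role}",
    )


def shell_coordination(
    profile: RDFProfile, bounds: tuple[float, float]
) -> float:
    """Coordination number 4*pi*rho * integral of g(r) r^2 dr over a shell.

    Trapezoidal quadrature on the binned profile, restricted to bins whose
    centers fall inside the bounds.
    """
    r_lo, r_hi = bounds
    if r_hi <= r_lo:
        raise ValueError(f"inverted shell bounds ({r_lo}, {r_hi})")
    if r_lo < profile.r[0] - profile.dr or r_hi > profile.r[-1] + profile.dr:
        raise ValueError("shell bounds outside the profile range")
    mask = (profile.r >= r_lo) & (profile.r <= r_hi)
    if mask.sum() < 2:
        raise ValueError("shell bounds contain fewer than two bins")
    integrand = profile.g[mask] * profile.r[mask] ** 2
    return float(4.0 * np.pi * profile.rho * np.trapezoid(integrand, profile.r[mask]))


def _smooth(g: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return g.astype(float)
    kernel = np.ones(window) / window
    return np.convolve(g, kernel, mode="same")


def _refine_peak(r: np.ndarray, g: np.ndarray, idx: int) -> float:
    """Sub-bin peak position from a parabola through three smoothed bins."""
    if idx == 0 or idx == len(g) - 1:
        return float(r[idx])
    y0, y1, y2 = g[idx - 1], g[idx], g[idx + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom >= 0:
        return float(r[idx])
    shift = 0.5 * (y0 - y2) / denom
    return float(r[idx] + np.clip(shift, -1.0, 1.0) * (r[1] - r[0]))


def find_shells(
    profile: RDFProfile,
    smoothing_window: int = 5,
    min_prominence: float = 0.5,
) -> ShellReport:
    """Locate the first two hydration-shell peaks and following minima.

    Works on a moving-average smoothed g(r). Only peaks with a prominence
    of at least ``min_prominence`` (in g units) count as shells, so
    sampling noise around the bulk level g = 1 is ignored. Peak positions
    are refined to sub-bin precision by a parabola through the smoothed
    maximum and its neighbors; each shell's coordination number integrates
    from the previous boundary to the shell's minimum.
    """
    if len(profile.g) == 0:
        raise ValueError("empty profile")
    gs = _smooth(profile.g, smoothing_window)
    peaks, _ = find_peaks(gs, prominence=min_prominence)
    flags: list[str] = []
    if len(peaks) == 0:
        return ShellReport(None, None, None, None, None, None, flags=["no_shells"])

    r = profile.r
    p1 = int(peaks[0])
    if len(peaks) >= 2:
        p2 = int(peaks[1])
        m1 = p1 + int(np.argmin(gs[p1 : p2 + 1]))
        after = gs[p2:]
        local_min = argrelextrema(after, np.less_equal, order=2)[0]
        local_min = local_min[local_min > 0]
        m2 = p2 + (int(local_min[0]) if len(local_min) else len(after) - 1)
        c1 = shell_coordination(profile, (r[0], r[m1]))
        c2 = shell_coordination(profile, (r[m1], r[m2]))
        return ShellReport(
            peak1=_refine_peak(r, gs, p1), min1=float(r[m1]),
            peak2=_refine_peak(r, gs, p2), min2=float(r[m2]),
            coordination1=c1, coordination2=c2, flags=flags,
        )

    # single shell: minimum is the lowest point after the only peak
    flags.append("first_shell_only")
    m1 = p1 + int(np.argmin(gs[p1:]))
    c1 = shell_coordination(profile, (r[0], r[m1]))
    return ShellReport(
        peak1=_refine_peak(r, gs, p1), min1=float(r[m1]),
        peak2=None, min2=None,
        coordination1=c1, coordination2=None, flags=flags,
    )


def superpose(
    x: np.ndarray, y: np.ndarray
) -> SuperpositionResult:
    """Optimal rigid-body superposition of Y onto X (Kabsch algorithm).

    Minimises the RMSD over proper rotations and translations; reflections
    are excluded by the determinant sign fix.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"coordinate sets differ in shape: {x.shape} vs {y.shape}")
    if x.ndim != 2 or x.shape[1] != 3 or x.shape[0] < 3:
        raise ValueError("need at least 3 atoms with 3 coordinates each")

    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    h = yc.T @ xc
    u, s, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    diag = np.diag([1.0, 1.0, d])
    rot = vt.T @ diag @ u.T
    y_fit = yc @ rot.T
    rmsd = float(np.sqrt(np.mean(np.sum((y_fit - xc) ** 2, axis=1))))
    translation = x.mean(axis=0) - rot @ y.mean(axis=0)
    return SuperpositionResult(rmsd=rmsd, rotation=rot, translation=translation)


def pairwise_rmsd(coords: list[np.ndarray]) -> np.ndarray:
    n = len(coords)
    mat = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            r = superpose(coords[i], coords[j]).rmsd
            mat[i, j] = mat[j, i] = r
    return mat


def cluster_frames(
    frames: list[Frame],
    selection_role: str | None = None,
    cutoff: float = 2.5,
) -> ClusterAssignment:
    """Greedy neighbor-count (GROMOS-style) RMSD clustering of frames.

    Repeatedly pick the unassigned frame with the most unassigned neighbors
    within ``cutoff`` RMSD as a cluster centroid, assign it and its
    neighbors, and repeat. Ties go to the lowest frame index. The default
    selection is all non-hydrogen atoms.
    """
    if not frames:
        raise ValueError("no frames to cluster")
    coords = []
    for frame in frames:
        if selection_role is None:
            idx = np.flatnonzero(frame.elements != "H")
        else:
            idx = frame.select(selection_role)
        if len(idx) == 0:
            raise ValueError("empty atom selection for clustering")
        coords.append(frame.coords[idx])

    n = len(frames)
    mat = pairwise_rmsd(coords)
    neighbors = mat <= cutoff  # includes self on the diagonal

    labels = np.full(n, -1, dtype=int)
    centroids: list[int] = []
    members: list[list[int]] = []
    unassigned = np.ones(n, dtype=bool)
    cluster_id = 0
    while unassigned.any():
        counts = (neighbors & unassigned).sum(axis=1)
        counts[~unassigned] = -1
        center = int(np.argmax(counts))  # argmax takes the lowest index on ties
        group = np.flatnonzero(neighbors[center] & unassigned)
        labels[group] = cluster_id
        unassigned[group] = False
        centroids.append(center)
        members.append(group.tolist())
        cluster_id += 1

    # order clusters by decreasing size, ties by lowest centroid index
    order = sorted(
        range(cluster_id), key=lambda c: (-len(members[c]), centroids[c])
    )
    remap = {old: new for new, old in enumerate(order)}
    labels = np.array([remap[l] for l in labels])
    centroids = [centroids[c] for c in order]
    members = [sorted(members[c]) for c in order]
    return ClusterAssignment(
        labels=labels, centroids=centroids, members=members, cutoff=cutoff
    )
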