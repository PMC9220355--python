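"""Independent oracle implementations used only by the tests.

These deliberately avoid the code paths they check: RMSD via Horn's
quaternion eigenvalue method (the implementation uses Kabsch/SVD), and a
naive greedy neighbor-count clustering written as plain loops over a
precomputed distance matrix.
"""

from __future__ import annotations

import numpy as np


def quaternion_rmsd(x: np.ndarray, y: np.ndarray) -> float:
    """Minimal RMSD over proper rotations via the Horn quaternion method."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    m = yc.T @ xc
    sxx, sxy, sxz = m[0]
    syx, syy, syz = m[1]
    szx, szy, szz = m[2]
    k = np.array([
        [sxx + syy + szz, syz - szy, szx - sxz, sxy - syx],
        [syz - szy, sxx - syy - szz, sxy + syx, szx + sxz],
        [szx - sxz, sxy + syx, -sxx + syy - szz, syz + szy],
        [sxy - syx, szx + sxz, syz + szy, -sxx - syy + szz],
    ])
    lam = np.linalg.eigvalsh(k)[-1]
    sq = float(np.sum(xc**2) + np.sum(yc**2) - 2.0 * lam)
    return float(np.sqrt(max(sq, 0.0) / n))


def greedy_cluster(dist: np.ndarray, cutoff: float) -> list[list[int]]:
    """Naive greedy neighbor-count clustering from a full distance matrix.

    Returns clusters as member lists ordered by decreasing size, ties by
    lowest centroid index (members sorted).
    """
    n = len(dist)
    remaining = set(range(n))
    raw = []  # (centroid, members)
    while remaining:
        best, best_count = None, -1
        for i in sorted(remaining):
            count = sum(1 for j in remaining if dist[i][j] <= cutoff)
            if count > best_count:
                best, best_count = i, count
        members = [j for j in sorted(remaining) if dist[best][j] <= cutoff]
        raw.append((best, members))
        remaining -= set(members)
    raw.sort(key=lambda cm: (-len(cm[1]), cm[0]))
    return [members for _, members in raw]
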