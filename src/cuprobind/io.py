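"""Trajectory and table I/O.

Trajectories travel as multi-frame XYZ plus a JSON sidecar carrying what
XYZ cannot: orthorhombic box lengths and per-atom role tags. XYZ frames
are read through MDAnalysis.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .hydration import Frame
from .kinetics import DoseResponseSeries


def write_xyz(frames: list[Frame], xyz_path, meta_path=None) -> None:
    """Write frames as multi-frame XYZ with an optional JSON sidecar."""
    xyz_path = Path(xyz_path)
    with open(xyz_path, "w") as fh:
        for i, frame in enumerate(frames):
            fh.write(f"{len(frame.coords)}\n")
            fh.write(f"frame {i}\n")
            for el, (x, y, z) in zip(frame.elements, frame.coords):
                fh.write(f"{el} {x:.10f} {y:.10f} {z:.10f}\n")
    if meta_path is not None:
        first = frames[0]
        meta = {
            "roles": list(first.roles),
            "box": None if first.box is None else list(map(float, first.box)),
        }
        with open(meta_path, "w") as fh:
            json.dump(meta, fh, indent=1)


def read_xyz(xyz_path, meta_path=None) -> list[Frame]:
    """Read a multi-frame XYZ trajectory (via MDAnalysis) plus sidecar.

    Without a sidecar, roles default to the element symbols and frames are
    non-periodic.
    """
    import MDAnalysis as mda

    u = mda.Universe(str(xyz_path), format="XYZ")
    elements = np.array([a.name for a in u.atoms], dtype=object)
    if meta_path is not None:
        with open(meta_path) as fh:
            meta = json.load(fh)
        roles = np.array(meta["roles"], dtype=object)
        if len(roles) != len(elements):
            raise ValueError(
                f"sidecar lists {len(roles)} roles for {len(elements)} atoms"
            )
        box = None if meta.get("box") is None else np.array(meta["box"], dtype=float)
    else:
        roles = elements.copy()
        box = None
    frames = []
    for _ in u.trajectory:
        frames.append(
            Frame(
                coords=u.atoms.positions.astype(float).copy(),
                elements=elements.copy(),
                roles=roles.copy(),
                box=None if box is None else box.copy(),
            )
        )
    return frames


def read_dose_response_csv(path) -> list[DoseResponseSeries]:
    """Read dose-response series: inhibitor_id, concentration_mM, activity.

    Replicates (repeated concentrations) are averaged before fitting.
    """
    df = pd.read_csv(path)
    required = {"inhibitor_id", "concentration_mM", "activity"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"dose-response table is missing columns {sorted(missing)}")
    out = []
    for inhibitor_id, grp in df.groupby("inhibitor_id", sort=True):
        mean = grp.groupby("concentration_mM", sort=True)["activity"].mean()
        out.append(
            DoseResponseSeries(
                inhibitor_id=str(inhibitor_id),
                concentrations=mean.index.to_numpy(dtype=float),
                activities=mean.to_numpy(dtype=float),
            )
        )
    return out


def read_traces_csv(path) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Read assay traces: series_id, time_s, value."""
    df = pd.read_csv(path)
    required = {"series_id", "time_s", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trace table is missing columns {sorted(missing)}")
    out = {}
    for sid, grp in df.groupby("series_id", sort=True):
        grp = grp.sort_values("time_s")
        out[str(sid)] = (
            grp["time_s"].to_numpy(dtype=float),
            grp["value"].to_numpy(dtype=float),
        )
    return out
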