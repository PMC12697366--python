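"""Plain-text readers and writers for trajectories, curves, catalogs and fits.

Trajectories go to CSV (columns t, x) with a JSON sidecar carrying the
metadata (form, mu, D, dt, seed, constraint, diverged).  External
one-column time series (plus a stated sampling interval) are wrapped into
:class:`~critbif.engine.Trajectory` so the avalanche and relaxation
diagnostics apply to empirical data unchanged.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .engine import Trajectory

__all__ = [
    "write_trajectory",
    "read_trajectory",
    "load_series",
    "write_catalog",
    "write_json_report",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def write_trajectory(traj: Trajectory, path) -> Path:
    path = Path(path)
    pd.DataFrame({"t": traj.t, "x": traj.x}).to_csv(path, index=False)
    _sidecar(path).write_text(json.dumps(traj.meta, indent=1, default=float))
    return path


def read_trajectory(path) -> Trajectory:
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    sc = _sidecar(path)
    if sc.exists():
        meta = json.loads(sc.read_text())
    return Trajectory(t=df["t"].to_numpy(), x=df["x"].to_numpy(), meta=meta)


def load_series(path, dt: float, meta: dict | None = None) -> Trajectory:
    """Wrap a user-supplied one-column plain-text series sampled at ``dt``.

    Accepts a bare column of numbers or a CSV whose first column is the
    series (a header line is detected and skipped).
    """
    path = Path(path)
    try:
        x = np.loadtxt(path, delimiter=",", usecols=0, ndmin=1)
    except ValueError:
        x = np.loadtxt(path, delimiter=",", usecols=0, skiprows=1, ndmin=1)
    t = np.arange(len(x)) * dt
    m = {"source": str(path), "dt": dt, "record_stride": 1}
    if meta:
        m.update(meta)
    return Trajectory(t=t, x=x, meta=m)


def write_catalog(catalog, path) -> Path:
    path = Path(path)
    dt = catalog.meta.get("dt", np.nan)
    stride = catalog.meta.get("record_stride", 1)
    pd.DataFrame({
        "start_time": catalog.start_indices * dt * stride,
        "duration": catalog.durations,
        "size": catalog.sizes,
    }).to_csv(path, index=False)
    return path


def write_json_report(obj: dict, path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(obj, indent=1, default=float))
    return path
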