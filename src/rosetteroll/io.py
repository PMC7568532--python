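"""File formats: trajectory CSV, velocity-field CSV, frame HDF5, JSON reports.

All on-disk units are fixed: um for lengths, s for time, rad for angles
(physical-model modules convert to SI internally).  The trajectory CSV
dialect is comma-separated, "." decimal, UTF-8, with a mandatory header
``t,x,y,z`` and an optional ``state`` column.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .rotation3d import VelocityField
from .trajectory import Trajectory

__all__ = [
    "read_trajectory",
    "write_trajectory",
    "read_velocity_field",
    "write_velocity_field",
    "read_frames",
    "write_frames",
    "write_json_report",
]

_UNITS = {"t": "s", "x": "um", "y": "um", "z": "um"}


def write_trajectory(traj: Trajectory, path: str | Path, sidecar: bool = True) -> Path:
    """Write a trajectory CSV (``t,x,y,z[,state]``) plus a units sidecar YAML."""
    path = Path(path)
    df = pd.DataFrame(
        {
            "t": traj.times,
            "x": traj.positions[:, 0],
            "y": traj.positions[:, 1],
            "z": traj.positions[:, 2],
        }
    )
    if traj.states is not None:
        df["state"] = traj.states
    df.to_csv(path, index=False, float_format="%.9g")
    if sidecar:
        meta = {"units": _UNITS, "unit_id": traj.unit_id, "kind": traj.kind}
        path.with_suffix(".yaml").write_text(yaml.safe_dump(meta, sort_keys=True))
    return path


def read_trajectory(
    path: str | Path, unit_id: str | None = None, kind: str | None = None
) -> Trajectory:
    """Read a trajectory CSV; malformed rows are dropped with a line log.

    Raises a schema error naming any missing column; non-monotone times
    raise a validation error (from the Trajectory constructor).
    """
    path = Path(path)
    df = pd.read_csv(path)
    missing = [c for c in ("t", "x", "y", "z") if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing required column(s) {missing}")
    numeric = df[["t", "x", "y", "z"]].apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().any(axis=1)
    if bad.any():
        lines = [int(i) + 2 for i in df.index[bad]]  # +2: header + 1-based
        warnings.warn(f"{path.name}: rejected malformed row(s) at line(s) {lines}", stacklevel=2)
        df = df[~bad]
        numeric = numeric[~bad]
    meta = {}
    sidecar = path.with_suffix(".yaml")
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
    states = list(df["state"]) if "state" in df.columns else None
    times = numeric["t"].to_numpy()
    positions = numeric[["x", "y", "z"]].to_numpy()
    kw = {
        "unit_id": unit_id or meta.get("unit_id", path.stem),
        "kind": kind or meta.get("kind", "rosette"),
    }
    dt = np.diff(times)
    if np.any(dt <= 0):
        raise ValueError(f"{path.name}: times must be strictly increasing")
    med = np.median(dt)
    if np.any(np.abs(dt - med) > 0.01 * med):
        # gaps (e.g. from rejected rows): interpolate back onto a uniform grid
        traj = Trajectory.resample_uniform(times, positions, dt=med, **kw)
        if states is not None:
            idx = np.searchsorted(times, traj.times, side="left")
            traj.states = [states[min(i, len(states) - 1)] for i in idx]
        return traj
    return Trajectory(times=times, positions=positions, states=states, **kw)


def write_velocity_field(field: VelocityField, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        {
            "x": field.x,
            "y": field.y,
            "vx": field.vx,
            "vy": field.vy,
            "w": field.weights,
            "valid": field.valid.astype(int),
        }
    ).to_csv(path, index=False, float_format="%.9g")
    return path


def read_velocity_field(
    path: str | Path, focal_plane_z: float = 0.0, focal_depth: float = np.inf
) -> VelocityField:
    df = pd.read_csv(path)
    missing = [c for c in ("x", "y", "vx", "vy", "w", "valid") if c not in df.columns]
    if missing:
        raise ValueError(f"{Path(path).name}: missing column(s) {missing}")
    return VelocityField(
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        vx=df["vx"].to_numpy(float),
        vy=df["vy"].to_numpy(float),
        weights=df["w"].to_numpy(float),
        focal_plane_z=focal_plane_z,
        focal_depth=focal_depth,
        valid=df["valid"].to_numpy(bool),
        empty=len(df) == 0,
    )


def write_frames(frames: np.ndarray, path: str | Path, pixel_size: float) -> Path:
    """Store a (T, H, W) uint8 frame stack in HDF5 with a pixel-size attribute."""
    path = Path(path)
    with h5py.File(path, "w") as f:
        ds = f.create_dataset("frames", data=np.asarray(frames, dtype=np.uint8))
        ds.attrs["pixel_size_um"] = float(pixel_size)
    return path


def read_frames(path: str | Path) -> tuple[np.ndarray, float]:
    with h5py.File(path, "r") as f:
        ds = f["frames"]
        return ds[...], float(ds.attrs["pixel_size_um"])


def write_json_report(data: dict, path: str | Path) -> Path:
    """Deterministic JSON (sorted keys, fixed float repr via json defaults)."""
    path = Path(path)

    def _default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    path.write_text(json.dumps(data, indent=2, sort_keys=True, default=_default) + "\n")
    return path
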