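"""Time-stamped 3D trajectory container shared across the pipeline."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Trajectory"]


@dataclass
class Trajectory:
    """A single dispersal unit's track: times (s) and positions (um).

    ``kind`` distinguishes rosette aggregates from solitary swarmer cells;
    ``states`` optionally carries per-sample motor-state labels ("CW",
    "CCW" or "NA").  Sampling must be uniform to within 1% of the median
    time step; call :meth:`resample_uniform` first otherwise.
    """

    times: np.ndarray
    positions: np.ndarray
    unit_id: str = "unit-0"
    kind: str = "rosette"
    states: list | None = field(default=None)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.positions = np.asarray(self.positions, dtype=float)
        if self.times.ndim != 1 or len(self.times) < 2:
            raise ValueError("trajectory needs at least 2 samples")
        if self.positions.shape != (len(self.times), 3):
            raise ValueError("positions must be (n, 3) matching times")
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.positions)):
            raise ValueError("times and positions must be finite")
        dt = np.diff(self.times)
        if np.any(dt <= 0):
            raise ValueError("times must be strictly increasing")
        med = np.median(dt)
        if np.any(np.abs(dt - med) > 0.01 * med):
            raise ValueError(
                "non-uniform sampling (>1% jitter); use resample_uniform first"
            )
        if self.states is not None and len(self.states) != len(self.times):
            raise ValueError("states must match times in length")
        if self.kind not in ("rosette", "swarmer"):
            raise ValueError(f"unknown trajectory kind {self.kind!r}")

    @property
    def dt(self) -> float:
        return float(np.median(np.diff(self.times)))

    @property
    def duration(self) -> float:
        return float(self.times[-1] - self.times[0])

    def xy(self) -> np.ndarray:
        return self.positions[:, :2]

    @staticmethod
    def resample_uniform(
        times: np.ndarray, positions: np.ndarray, dt: float | None = None, **kw
    ) -> "Trajectory":
        """Linear-interpolate an irregular track onto a uniform grid."""
        times = np.asarray(times, float)
        positions = np.asarray(positions, float)
        if dt is None:
            dt = float(np.median(np.diff(times)))
        grid = np.arange(times[0], times[-1] + 0.5 * dt, dt)
        out = np.column_stack([np.interp(grid, times, positions[:, k]) for k in range(3)])
        return Trajectory(times=grid, positions=out, **kw)
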