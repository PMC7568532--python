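"""Mean-squared displacement analysis and the ballistic-diffusive crossover.

Self-propelled dispersal units (rolling rosettes, swimming swarmer cells)
move ballistically on timescales shorter than the flagellar-motor
reversal time and diffusively beyond it.  The crossover lag time of the
ensemble MSD, obtained as the intersection of a quadratic fit at short
lags and a linear fit at long lags, estimates that reorientation
timescale.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "MsdCurve",
    "CrossoverFit",
    "compute_msd",
    "fit_crossover",
    "speed_stats",
    "SpeedStats",
]

MIN_TRACK_DURATION = 60.0  # s; tracks shorter than this are excluded from MSD


@dataclass(frozen=True)
class MsdCurve:
    """Ensemble MSD: lag grid (s), mean (um^2), SD across units, unit count."""

    lags: np.ndarray
    msd: np.ndarray
    sd: np.ndarray
    n_units: int

    def __post_init__(self) -> None:
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lag grid must be increasing")
        if np.any(self.msd < -1e-12):
            raise ValueError("MSD must be non-negative")


@dataclass(frozen=True)
class CrossoverFit:
    """Crossover of the quadratic (ballistic) and linear (diffusive) MSD fits.

    ``ballistic_coeff`` a (um^2/s^2) and ``diffusive_coeff`` b (um^2/s) solve
    ``a t^2 = b t`` at ``t_c = b / a``.  ``exponents`` are the free power-law
    slopes measured over each window (diagnostic only).
    """

    t_c: float
    ballistic_coeff: float
    diffusive_coeff: float
    ballistic_window: tuple
    diffusive_window: tuple
    exponents: tuple


def _single_track_msd(xy: np.ndarray, max_lag: int) -> np.ndarray:
    """Time-averaged squared displacement for lags 1..max_lag (frames).

    FFT-based: MSD(k) = <|r(t+k) - r(t)|^2>_t with all overlapping origins.
    """
    n = len(xy)
    nfft = 1 << (2 * n - 1).bit_length()
    sq = np.sum(xy**2, axis=1)
    # autocorrelation per component via FFT
    acf = np.zeros(n)
    for c in range(xy.shape[1]):
        f = np.fft.rfft(xy[:, c], nfft)
        acf += np.fft.irfft(f * np.conj(f), nfft)[:n]
    counts = n - np.arange(n)
    # sum_{t} sq[t] + sq[t+k] terms
    csum = np.cumsum(sq)
    total = csum[-1]
    sum_sq = np.empty(n)
    sum_sq[0] = 2.0 * total
    for k in range(1, n):
        sum_sq[k] = (total - csum[k - 1]) + (total - (csum[-1] - csum[n - k - 1]))
    msd = (sum_sq - 2.0 * acf) / counts
    return msd[1 : max_lag + 1]


def compute_msd(
    trajectories: list[Trajectory],
    max_lag: float | None = None,
    plane: str = "xy",
    min_duration: float = MIN_TRACK_DURATION,
) -> MsdCurve:
    """Ensemble 2D (or 3D) MSD with overlapping time-origin averaging.

    Each unit contributes its time-averaged MSD; the ensemble curve is the
    mean over units and the error bars the SD across units.  Tracks
    shorter than ``min_duration`` are dropped (short tracks bias the
    time average); lags longer than the shortest retained track are
    omitted with a warning.
    """
    if plane not in ("xy", "xyz"):
        raise ValueError("plane must be 'xy' or 'xyz'")
    kept = [t for t in trajectories if t.duration >= min_duration]
    if not kept:
        raise ValueError(
            f"no trajectory of duration >= {min_duration}s; pass min_duration=0 to keep all"
        )
    dts = {round(t.dt, 9) for t in kept}
    if len(dts) > 1:
        raise ValueError("trajectories must share a common frame interval")
    dt = kept[0].dt
    shortest = min(len(t.times) for t in kept) - 1
    if max_lag is None:
        lag_frames = shortest
    else:
        lag_frames = int(round(max_lag / dt))
        if lag_frames > shortest:
            warnings.warn(
                f"requested max lag {max_lag}s exceeds shortest track; truncating",
                stacklevel=2,
            )
            lag_frames = shortest
    curves = []
    for t in kept:
        pts = t.xy() if plane == "xy" else t.positions
        curves.append(_single_track_msd(pts, lag_frames))
    arr = np.array(curves)
    lags = dt * np.arange(1, lag_frames + 1)
    return MsdCurve(
        lags=lags,
        msd=arr.mean(axis=0),
        sd=arr.std(axis=0, ddof=1) if len(arr) > 1 else np.zeros(lag_frames),
        n_units=len(kept),
    )


def fit_crossover(
    curve: MsdCurve,
    ballistic_window: tuple = (0.0, 0.5),
    diffusive_window: tuple = (5.0, np.inf),
) -> CrossoverFit:
    """Crossover lag of quadratic and linear MSD fits.

    Fits ``MSD = a t^2`` on the ballistic window and ``MSD = b t`` on the
    diffusive window, both by least squares in log-log space with the
    exponent fixed, and intersects them: ``t_c = b / a``.
    """
    if ballistic_window[1] > diffusive_window[0]:
        raise ValueError("windows must be disjoint with ballistic below diffusive")
    mb = (curve.lags >= ballistic_window[0]) & (curve.lags <= ballistic_window[1])
    md = (curve.lags >= diffusive_window[0]) & (curve.lags <= diffusive_window[1])
    if mb.sum() < 2 or md.sum() < 2:
        raise ValueError("need >= 2 lags inside each fit window")
    if np.any(curve.msd[mb | md] <= 0):
        raise ValueError("MSD must be positive inside the fit windows")
    log_a = np.mean(np.log(curve.msd[mb]) - 2.0 * np.log(curve.lags[mb]))
    log_b = np.mean(np.log(curve.msd[md]) - np.log(curve.lags[md]))
    a = float(np.exp(log_a))
    b = float(np.exp(log_b))
    if a <= 0 or b <= 0:
        raise ValueError("non-positive fitted coefficients")

    def _slope(mask):
        return float(np.polyfit(np.log(curve.lags[mask]), np.log(curve.msd[mask]), 1)[0])

    return CrossoverFit(
        t_c=b / a,
        ballistic_coeff=a,
        diffusive_coeff=b,
        ballistic_window=tuple(ballistic_window),
        diffusive_window=(float(diffusive_window[0]), float(min(diffusive_window[1], curve.lags[-1]))),
        exponents=(_slope(mb), _slope(md)),
    )


@dataclass(frozen=True)
class SpeedStats:
    """Per-unit and ensemble speed statistics in the motile regime."""

    per_unit_mean: np.ndarray
    ensemble_mean: float
    ensemble_sd: float
    motile_fraction: float
    immotile_threshold: float


def speed_stats(
    trajectories: list[Trajectory],
    smoothing_window: int = 5,
    immotile_threshold: float = 0.5,
) -> SpeedStats:
    """Frame-wise speeds from central differences of smoothed positions.

    Intervals slower than ``immotile_threshold`` (um/s; pauses of the
    power source) are flagged and excluded from the motile-regime mean.
    Tracks shorter than the smoothing window are skipped with a warning.
    """
    if smoothing_window < 1:
        raise ValueError("smoothing window must be >= 1 frame")
    means = []
    n_motile = 0
    n_total = 0
    for t in trajectories:
        if len(t.times) <= smoothing_window + 2:
            warnings.warn(f"track {t.unit_id} shorter than smoothing window; skipped", stacklevel=2)
            continue
        pos = t.positions
        if smoothing_window > 1:
            kern = np.ones(smoothing_window) / smoothing_window
            pos = np.column_stack(
                [np.convolve(pos[:, k], kern, mode="valid") for k in range(3)]
            )
        v = np.gradient(pos, t.dt, axis=0)
        speed = np.linalg.norm(v[:, :2], axis=1)
        motile = speed > immotile_threshold
        n_motile += int(motile.sum())
        n_total += len(speed)
        if motile.any():
            means.append(float(speed[motile].mean()))
    if not means:
        raise ValueError("no motile interval found in any track")
    arr = np.array(means)
    return SpeedStats(
        per_unit_mean=arr,
        ensemble_mean=float(arr.mean()),
        ensemble_sd=float(arr.std(ddof=1)) if len(arr) > 1 else 0.0,
        motile_fraction=n_motile / max(n_total, 1),
        immotile_threshold=immotile_threshold,
    )
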