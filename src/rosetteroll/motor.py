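"""Flagellar motor-state inference from trajectory geometry.

The motor state (CW or CCW) of the single driving flagellum is not
directly observable; it is inferred from the chirality of the track.
Flagellar propulsion near a surface curves the path: a CW motor produces
CCW in-plane circulation and vice versa, so the sign of the mean signed
curvature of a segment labels its motor state.  Sharp heading changes
mark motor switches; the statistics of turning angles, state durations
and restoring times (a CW duration plus the consecutive CCW duration)
characterize the reorientation mechanism.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "MotorSegment",
    "SwitchEvent",
    "DurationStats",
    "MixtureFit",
    "detect_switches",
    "assign_motor_state",
    "turning_angle",
    "duration_and_restoring_stats",
    "fit_mixture",
]


@dataclass
class MotorSegment:
    """Interval of constant inferred motor state."""

    state: str  # "CW" | "CCW" | "undetermined"
    t_start: float
    t_end: float
    mean_curvature: float = np.nan

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("segment must have positive duration")

    @property
    def duration(self) -> float:
        return self.t_end - self.t_start

    @property
    def circulation(self) -> int:
        """+1 CCW circulation, -1 CW, 0 undetermined."""
        if not np.isfinite(self.mean_curvature) or self.mean_curvature == 0:
            return 0
        return 1 if self.mean_curvature > 0 else -1


@dataclass
class SwitchEvent:
    """A detected motor switch with its reorientation angle."""

    time: float
    direction: str  # "CW->CCW" | "CCW->CW" | "unknown"
    theta: float = np.nan
    flagged: bool = False  # True when adjacent states conflict (missed event?)

    def __post_init__(self) -> None:
        if np.isfinite(self.theta) and not 0.0 <= self.theta <= np.pi + 1e-9:
            raise ValueError("turning angle must lie in [0, pi]")


def _smoothed_kinematics(traj: Trajectory, window: int):
    from scipy.ndimage import uniform_filter1d

    pos = traj.xy()
    if window > 1:
        pos = uniform_filter1d(pos, window, axis=0, mode="nearest")
    v = np.gradient(pos, traj.dt, axis=0)
    a = np.gradient(v, traj.dt, axis=0)
    speed = np.linalg.norm(v, axis=1)
    return pos, v, a, speed


def signed_curvature(v: np.ndarray, a: np.ndarray, floor: float = 1e-9) -> np.ndarray:
    """Signed curvature kappa = (v x a)_z / |v|^3; positive = CCW turning."""
    cross = v[:, 0] * a[:, 1] - v[:, 1] * a[:, 0]
    s3 = np.maximum(np.linalg.norm(v, axis=1), floor) ** 3
    return cross / s3


def assign_motor_state(
    traj: Trajectory,
    t_start: float,
    t_end: float,
    smoothing_window: int = 5,
    speed_floor: float = 0.5,
    kappa_floor: float = 0.01,
) -> MotorSegment:
    """Motor state of one segment from its circulation sign.

    CCW circulation (mean signed curvature > 0) implies a CW motor and
    vice versa.  Segments shorter than 5 frames, or whose |mean curvature|
    falls below ``kappa_floor`` (1/um), are "undetermined" and excluded
    from downstream statistics.
    """
    m = (traj.times >= t_start) & (traj.times <= t_end)
    if m.sum() < 5:
        return MotorSegment("undetermined", t_start, t_end)
    _, v, a, speed = _smoothed_kinematics(traj, smoothing_window)
    mm = m & (speed > speed_floor)
    if mm.sum() < 5:
        return MotorSegment("undetermined", t_start, t_end)
    # mean signed curvature kappa = d(heading)/d(arclength), estimated by
    # regressing the unwrapped heading on time (robust against the noise
    # amplification of double differentiation)
    heading = np.unwrap(np.arctan2(v[mm, 1], v[mm, 0]))
    rate = float(np.polyfit(traj.times[mm], heading, 1)[0])
    kappa = rate / float(np.mean(speed[mm]))
    if abs(kappa) < kappa_floor:
        return MotorSegment("undetermined", t_start, t_end, kappa)
    state = "CW" if kappa > 0 else "CCW"  # CCW circulation -> CW motor
    return MotorSegment(state, t_start, t_end, kappa)


def detect_switches(
    traj: Trajectory,
    angle_threshold: float = np.pi / 2.0,
    speed_floor: float = 0.5,
    window: float = 0.25,
    smoothing_window: int = 5,
    kappa_floor: float = 0.01,
) -> tuple[list[SwitchEvent], list[MotorSegment]]:
    """Locate motor switches as sharp heading changes at speed minima.

    A switch is flagged where the heading rotates by more than
    ``angle_threshold`` across a sliding window of ``window`` seconds
    (evaluated only where the speed exceeds ``speed_floor``), and is
    placed at the local speed minimum of the excursion.  The intervals
    between switches become :class:`MotorSegment`'s with chirality-based
    states; consecutive segments with the SAME inferred state indicate a
    missed intermediate event and are flagged, not merged.
    """
    _, v, a, speed = _smoothed_kinematics(traj, smoothing_window)
    dt = traj.dt
    half = max(1, int(round(window / dt / 2)))
    n = len(speed)
    if not np.any(speed > speed_floor):
        warnings.warn(f"track {traj.unit_id} has no motile interval", stacklevel=2)
        return [], []
    # heading change over +-half frames
    vv = v / np.maximum(np.linalg.norm(v, axis=1, keepdims=True), 1e-12)
    dtheta = np.zeros(n)
    i0 = np.arange(half, n - half)
    cosang = np.clip(np.sum(vv[i0 - half] * vv[i0 + half], axis=1), -1.0, 1.0)
    dtheta[i0] = np.arccos(cosang)
    candidate = (dtheta > angle_threshold) & (np.arange(n) >= half) & (np.arange(n) < n - half)
    # group contiguous candidates, place event at the speed minimum
    events_idx = []
    i = 0
    while i < n:
        if candidate[i]:
            j = i
            while j + 1 < n and candidate[j + 1]:
                j += 1
            seg = slice(max(i - half, 0), min(j + half + 1, n))
            events_idx.append(int(np.argmin(speed[seg])) + seg.start)
            i = j + 1
        else:
            i += 1
    # merge events closer than the window
    merged = []
    for idx in events_idx:
        if merged and (idx - merged[-1]) * dt < window:
            if speed[idx] < speed[merged[-1]]:
                merged[-1] = idx
        else:
            merged.append(idx)

    times = traj.times
    bounds = [times[0]] + [times[i] for i in merged] + [times[-1]]
    segments = []
    for t0, t1 in zip(bounds[:-1], bounds[1:]):
        if t1 > t0:
            segments.append(
                assign_motor_state(
                    traj, t0, t1, smoothing_window, speed_floor, kappa_floor
                )
            )
    events = []
    for k, idx in enumerate(merged):
        ev = SwitchEvent(time=times[idx], direction="unknown")
        th = turning_angle(traj, ev)
        ev.theta = th if th is not None else np.nan
        if traj.kind == "swarmer":
            # solitary cells reveal the switch direction through the turn
            # geometry: reversal (theta ~ pi) is CW->CCW, flick CCW->CW
            if np.isfinite(ev.theta):
                ev.direction = "CW->CCW" if ev.theta > 3.0 * np.pi / 4.0 else "CCW->CW"
        else:
            before = segments[k].state if k < len(segments) else "undetermined"
            after = segments[k + 1].state if k + 1 < len(segments) else "undetermined"
            if "undetermined" not in (before, after) and before != after:
                ev.direction = f"{before}->{after}"
            elif "undetermined" not in (before, after):
                # same chirality on both sides: a missed intermediate switch
                ev.flagged = True
        events.append(ev)
    return events, segments


def turning_angle(
    traj: Trajectory,
    event: SwitchEvent,
    pre_window: float = 0.5,
    post_window: float = 0.5,
    exclude_frames: int = 2,
) -> float | None:
    """Angle between mean pre- and post-switch velocity directions, in [0, pi].

    Windows of ``pre_window``/``post_window`` seconds on each side exclude
    ``exclude_frames`` frames around the switch instant; events whose
    windows run past the track ends return None (dropped by callers).
    """
    dt = traj.dt
    t = event.time
    v = np.gradient(traj.xy(), dt, axis=0)
    pre = (traj.times >= t - pre_window) & (traj.times <= t - exclude_frames * dt)
    post = (traj.times >= t + exclude_frames * dt) & (traj.times <= t + post_window)
    if pre.sum() < 1 or post.sum() < 1:
        return None
    if traj.times[0] > t - pre_window or traj.times[-1] < t + post_window:
        return None
    v1 = v[pre].mean(axis=0)
    v2 = v[post].mean(axis=0)
    n1, n2 = np.linalg.norm(v1), np.linalg.norm(v2)
    if n1 < 1e-12 or n2 < 1e-12:
        return None
    return float(np.arccos(np.clip(v1 @ v2 / (n1 * n2), -1.0, 1.0)))


@dataclass
class DurationStats:
    """Per-state motor durations and restoring times (s)."""

    cw: np.ndarray
    ccw: np.ndarray
    restoring: np.ndarray
    n_flagged: int = 0

    @property
    def all_durations(self) -> np.ndarray:
        return np.concatenate([self.cw, self.ccw])


def duration_and_restoring_stats(segments: list[MotorSegment]) -> DurationStats:
    """Duration samples per motor state and overlapping restoring times.

    The restoring time is the time for the motor to return to a state:
    the sum of a CW duration and a consecutive CCW duration.  Both
    pairings (CW_i + CCW_i and CCW_i + CW_{i+1}) are used, so consecutive
    triples contribute two overlapping samples.  Undetermined segments
    break pairing chains; same-state neighbours are counted as flagged.
    """
    if len(segments) < 2:
        raise ValueError("need at least 2 segments")
    cw = np.array([s.duration for s in segments if s.state == "CW"])
    ccw = np.array([s.duration for s in segments if s.state == "CCW"])
    restoring = []
    n_flagged = 0
    for s1, s2 in zip(segments[:-1], segments[1:]):
        if "undetermined" in (s1.state, s2.state):
            continue
        if s1.state == s2.state:
            n_flagged += 1
            continue
        restoring.append(s1.duration + s2.duration)
    return DurationStats(cw=cw, ccw=ccw, restoring=np.array(restoring), n_flagged=n_flagged)


@dataclass(frozen=True)
class MixtureFit:
    """Maximum-likelihood mixture fit: weights, parameters, log-likelihood."""

    family: str
    weights: np.ndarray
    params: np.ndarray  # gaussians: (k, 2) mean/sd; exponentials: (k,) means
    log_likelihood: float
    converged: bool
    n_iter: int = 0


def _em_exponential(x: np.ndarray, k: int, rng: np.random.Generator, n_init: int = 5):
    best = None
    n = len(x)
    for _ in range(n_init):
        q = np.quantile(x, np.linspace(0.2, 0.8, k))
        means = q * rng.uniform(0.5, 2.0, k)
        w = np.full(k, 1.0 / k)
        ll_prev = -np.inf
        converged = False
        for it in range(500):
            lam = 1.0 / np.maximum(means, 1e-12)
            logp = np.log(w)[None, :] + np.log(lam)[None, :] - x[:, None] * lam[None, :]
            mx = logp.max(axis=1, keepdims=True)
            p = np.exp(logp - mx)
            norm = p.sum(axis=1, keepdims=True)
            r = p / norm
            ll = float(np.sum(mx[:, 0] + np.log(norm[:, 0])))
            w = r.mean(axis=0)
            means = (r * x[:, None]).sum(axis=0) / np.maximum(r.sum(axis=0), 1e-300)
            if abs(ll - ll_prev) < 1e-10 * max(abs(ll), 1.0):
                converged = True
                break
            ll_prev = ll
        if best is None or ll > best[0]:
            best = (ll, w, means, converged, it + 1)
    return best


def fit_mixture(
    samples: np.ndarray,
    family: str = "gaussian",
    k: int = 2,
    seed: int = 0,
    reflect: tuple | None = None,
) -> MixtureFit:
    """Maximum-likelihood Gaussian or exponential mixture.

    ``reflect=(lo, hi)`` mirrors the samples at both boundaries before
    fitting (used for turning angles supported on [0, pi], where density
    mass piles up at the reversal boundary); components whose means fall
    outside [lo, hi] are dropped and the weights renormalized.

    Deterministic for a given seed; raises RuntimeError if no restart
    converges.  Degenerate all-equal samples are handled by the variance
    floor (gaussian) or collapse to a point estimate (exponential).
    """
    x = np.asarray(samples, dtype=float)
    if family not in ("gaussian", "exponential"):
        raise ValueError("family must be 'gaussian' or 'exponential'")
    if k not in (1, 2, 3):
        raise ValueError("k must be 1, 2 or 3")
    if len(x) < 2 * k:
        raise ValueError("too few samples for the requested mixture order")
    fit_x = x
    if reflect is not None:
        lo, hi = reflect
        fit_x = np.concatenate([x, 2 * lo - x, 2 * hi - x])
    if family == "gaussian":
        from sklearn.mixture import GaussianMixture

        gm = GaussianMixture(
            n_components=k,
            covariance_type="spherical",
            n_init=5,
            random_state=seed,
            reg_covar=1e-10,
            max_iter=500,
        )
        gm.fit(fit_x[:, None])
        if not gm.converged_:
            raise RuntimeError(
                f"gaussian mixture EM failed to converge (ll={gm.lower_bound_:.4g})"
            )
        w = gm.weights_
        params = np.column_stack([gm.means_[:, 0], np.sqrt(gm.covariances_)])
        ll = float(gm.score(x[:, None]) * len(x))
        fit = MixtureFit(family, w, params, ll, True, int(gm.n_iter_))
    else:
        if np.any(x <= 0):
            raise ValueError("exponential mixture needs positive samples")
        rng = np.random.default_rng(seed)
        ll, w, means, converged, it = _em_exponential(fit_x, k, rng)
        if not converged:
            raise RuntimeError(f"exponential mixture EM failed to converge (ll={ll:.4g})")
        order = np.argsort(means)
        fit = MixtureFit(family, w[order], means[order], ll, converged, it)
    if reflect is not None:
        lo, hi = reflect
        centers = fit.params[:, 0] if family == "gaussian" else fit.params
        keep = (centers >= lo - 1e-9) & (centers <= hi + 1e-9)
        if keep.any():
            w = fit.weights[keep] / fit.weights[keep].sum()
            params = fit.params[keep]
            fit = MixtureFit(fit.family, w, params, fit.log_likelihood, fit.converged, fit.n_iter)
    return fit
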