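"""Translation-rotation coupling near the wall: rolling statistics.

A rosette rolling on the bottom surface translates perpendicular to its
in-plane rotation axis.  Two statistics quantify this coupling:

* the angle ``beta`` between the in-plane rotation axis and the in-plane
  translation, measured counter-clockwise from the axis; ideal forward
  rolling gives ``beta = 3 pi / 2``.  The polarity
  ``P = 2 (rho_max - rho_min) / (rho_max + rho_min)`` of the circular
  density ``rho(beta)`` measures how strongly the coupling is locked.
* the slipping ratio ``Q = u_perp / (omega_{x-y} R)``: 1 for no-slip
  rolling, 0 for spinning in place.

Fits of ``Q`` against the scaled wall gap ``d/R`` (exponential decay,
bootstrap confidence bounds) and group comparisons (one-way ANOVA and an
ordinary-least-squares slope test, both computed from their defining
sums) follow the field's standard workflow.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import optimize, stats

from .trajectory import Trajectory

__all__ = [
    "RollingCoupling",
    "BetaDistribution",
    "couple_intervals",
    "beta_distribution",
    "QGapFit",
    "fit_q_vs_gap",
    "GroupComparison",
    "compare_groups",
]


@dataclass(frozen=True)
class RollingCoupling:
    """Per-interval coupling sample linking translation to rotation."""

    t_mid: float
    u_xy: np.ndarray
    u_perp: float
    omega_inplane: float
    axis: np.ndarray
    beta: float
    q: float
    d_over_R: float

    def __post_init__(self) -> None:
        if self.q < 0:
            raise ValueError("Q must be non-negative")
        if not 0.0 <= self.beta < 2.0 * np.pi:
            raise ValueError("beta must lie in [0, 2 pi)")
        if self.u_perp > np.linalg.norm(self.u_xy) + 1e-9:
            raise ValueError("u_perp cannot exceed |u_xy|")


def couple_intervals(
    traj: Trajectory,
    omega_series: np.ndarray,
    radius: float,
    gap: float | np.ndarray,
    interval: float = 1.0,
    omega_floor: float = 0.05,
) -> list[RollingCoupling]:
    """Rolling-coupling samples over fixed time intervals.

    Per interval: mean in-plane velocity from the net displacement, mean
    in-plane rotation axis from the angular-velocity series, ``beta``
    measured CCW from the axis to the velocity, ``u_perp`` the velocity
    component perpendicular to the axis and ``Q = u_perp/(omega R)``.
    Intervals whose in-plane rotation speed falls below ``omega_floor``
    (rad/s) are excluded (Q undefined for pure translation noise).
    """
    if len(omega_series) != len(traj.times):
        raise ValueError("omega series must align with trajectory samples")
    gaps = np.broadcast_to(np.asarray(gap, dtype=float), (len(traj.times),))
    t0 = traj.times[0]
    n_int = int(np.floor((traj.times[-1] - t0) / interval))
    out: list[RollingCoupling] = []
    for i in range(n_int):
        m = (traj.times >= t0 + i * interval) & (traj.times <= t0 + (i + 1) * interval)
        idx = np.flatnonzero(m)
        if len(idx) < 2:
            continue
        dt_span = traj.times[idx[-1]] - traj.times[idx[0]]
        u_xy = (traj.positions[idx[-1], :2] - traj.positions[idx[0], :2]) / dt_span
        # trapezoidal mean, consistent with the displacement being the
        # trapezoidal integral of the velocity over the same samples
        om_xy = np.trapezoid(omega_series[m, :2], traj.times[m], axis=0) / dt_span
        om_mag = float(np.linalg.norm(om_xy))
        if om_mag < omega_floor:
            continue
        axis = om_xy / om_mag
        # beta: CCW angle from axis to u_xy
        beta = float(
            (np.arctan2(u_xy[1], u_xy[0]) - np.arctan2(axis[1], axis[0])) % (2.0 * np.pi)
        )
        u_perp = float(abs(u_xy[0] * (-axis[1]) + u_xy[1] * axis[0]))
        q = u_perp / (om_mag * radius)
        out.append(
            RollingCoupling(
                t_mid=float(t0 + (i + 0.5) * interval),
                u_xy=u_xy,
                u_perp=u_perp,
                omega_inplane=om_mag,
                axis=axis,
                beta=beta,
                q=q,
                d_over_R=float(gaps[m].mean() / radius),
            )
        )
    return out


@dataclass(frozen=True)
class BetaDistribution:
    """Smoothed circular density of beta with its polarity."""

    bin_centers: np.ndarray
    density: np.ndarray
    bandwidth: float
    polarity: float
    n_samples: int
    low_confidence: bool

    def __post_init__(self) -> None:
        width = 2.0 * np.pi / len(self.bin_centers)
        total = float(np.sum(self.density) * width)
        if abs(total - 1.0) > 1e-6:
            raise ValueError("density must integrate to 1")
        if not 0.0 <= self.polarity <= 2.0:
            raise ValueError("polarity must lie in [0, 2]")


def beta_distribution(
    samples: np.ndarray,
    bins: int = 36,
    bandwidth: float = np.pi / 12.0,
) -> BetaDistribution:
    """Circular histogram of beta with wrapped-Gaussian kernel smoothing.

    ``rho_max`` and ``rho_min`` are taken from the smoothed density (a raw
    histogram makes ``rho_min`` noise-dominated), giving the polarity
    ``P = 2 (rho_max - rho_min)/(rho_max + rho_min)``.  ``bandwidth`` is
    the kernel SD in radians; 0 disables smoothing.  Fewer than 30
    samples flags the polarity as low-confidence.
    """
    x = np.mod(np.asarray(samples, dtype=float), 2.0 * np.pi)
    if len(x) == 0:
        raise ValueError("no beta samples")
    edges = np.linspace(0.0, 2.0 * np.pi, bins + 1)
    width = edges[1] - edges[0]
    hist, _ = np.histogram(x, bins=edges)
    dens = hist / (len(x) * width)
    if bandwidth > 0:
        centers = 0.5 * (edges[:-1] + edges[1:])
        dtheta = centers[:, None] - centers[None, :]
        dtheta = np.angle(np.exp(1j * dtheta))
        kern = np.exp(-0.5 * (dtheta / bandwidth) ** 2)
        kern /= kern.sum(axis=1, keepdims=True)
        dens = kern @ dens
        dens /= dens.sum() * width
    rho_max, rho_min = float(dens.max()), float(dens.min())
    P = 2.0 * (rho_max - rho_min) / (rho_max + rho_min) if rho_max > 0 else 0.0
    low = len(x) < 30
    if low:
        warnings.warn(
            f"only {len(x)} beta samples; polarity flagged low-confidence", stacklevel=2
        )
    return BetaDistribution(
        bin_centers=0.5 * (edges[:-1] + edges[1:]),
        density=dens,
        bandwidth=bandwidth,
        polarity=P,
        n_samples=len(x),
        low_confidence=low,
    )


@dataclass(frozen=True)
class QGapFit:
    """Exponential fit Q = a exp(-b d/R) with bootstrap 95% bounds."""

    a: float
    b: float
    a_ci: tuple
    b_ci: tuple
    residual_sd: float
    n_boot: int


def fit_q_vs_gap(
    d_over_R: np.ndarray,
    q: np.ndarray,
    n_boot: int = 1000,
    seed: int = 0,
) -> QGapFit:
    """Nonlinear least squares of ``Q = a exp(-b x)`` on (d/R, Q) samples.

    Confidence bounds are parametric-bootstrap percentiles: synthetic
    datasets are drawn from the fitted curve plus Gaussian residual noise
    and refitted.  Needs at least 3 distinct gap values.
    """
    x = np.asarray(d_over_R, dtype=float)
    y = np.asarray(q, dtype=float)
    if len(np.unique(np.round(x, 9))) < 3:
        raise ValueError("need >= 3 distinct d/R values")

    def model(x_, a_, b_):
        return a_ * np.exp(-b_ * x_)

    try:
        p0 = (max(y.max(), 1e-3), 1.0)
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"exponential fit failed: {exc}; residuals {y - y.mean()}") from exc
    resid = y - model(x, *popt)
    sd = float(np.std(resid, ddof=2)) if len(y) > 2 else 0.0
    rng = np.random.default_rng(seed)
    boots = []
    for _ in range(n_boot):
        yb = model(x, *popt) + rng.normal(0.0, sd, len(y))
        try:
            pb, _ = optimize.curve_fit(model, x, yb, p0=popt, maxfev=5000)
            boots.append(pb)
        except RuntimeError:
            continue
    if boots:
        arr = np.array(boots)
        a_ci = tuple(np.percentile(arr[:, 0], [2.5, 97.5]))
        b_ci = tuple(np.percentile(arr[:, 1], [2.5, 97.5]))
    else:
        a_ci = b_ci = (np.nan, np.nan)
    return QGapFit(
        a=float(popt[0]), b=float(popt[1]), a_ci=a_ci, b_ci=b_ci, residual_sd=sd, n_boot=len(boots)
    )


@dataclass(frozen=True)
class GroupComparison:
    """One-way ANOVA across gap bins plus an OLS slope test."""

    f_statistic: float
    anova_p: float
    slope: float
    slope_p: float
    significant: bool
    alpha: float = 0.05


def compare_groups(groups: dict[float, np.ndarray], alpha: float = 0.05) -> GroupComparison:
    """Compare Q across d/R bins.

    ``groups`` maps a bin's representative d/R to its Q samples.  The
    one-way ANOVA decomposition (between/within sums of squares) and the
    ordinary-least-squares slope t-test are computed from their defining
    formulas; p-values come from the F and t distributions.  Differences
    are called significant at ``alpha`` (default 0.05).
    """
    keys = sorted(groups)
    ys = [np.asarray(groups[k], dtype=float) for k in keys]
    if len(ys) < 2 or any(len(y) < 3 for y in ys):
        raise ValueError("need >= 2 groups with >= 3 samples each")
    all_y = np.concatenate(ys)
    grand = all_y.mean()
    n_tot = len(all_y)
    k = len(ys)
    ss_between = sum(len(y) * (y.mean() - grand) ** 2 for y in ys)
    ss_within = sum(((y - y.mean()) ** 2).sum() for y in ys)
    df_b, df_w = k - 1, n_tot - k
    if ss_within <= 0:
        raise ValueError("zero within-group variance: degenerate input")
    F = (ss_between / df_b) / (ss_within / df_w)
    p_anova = float(stats.f.sf(F, df_b, df_w))

    xs = np.concatenate([np.full(len(y), kk) for kk, y in zip(keys, ys)])
    xbar, ybar = xs.mean(), all_y.mean()
    sxx = ((xs - xbar) ** 2).sum()
    slope = float(((xs - xbar) * (all_y - ybar)).sum() / sxx)
    intercept = ybar - slope * xbar
    resid = all_y - (intercept + slope * xs)
    s2 = (resid**2).sum() / (n_tot - 2)
    se = np.sqrt(s2 / sxx)
    tstat = slope / se if se > 0 else np.inf
    p_slope = float(2.0 * stats.t.sf(abs(tstat), n_tot - 2))
    return GroupComparison(
        f_statistic=float(F),
        anova_p=p_anova,
        slope=slope,
        slope_p=p_slope,
        significant=bool(p_anova < alpha or p_slope < alpha),
        alpha=alpha,
    )
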