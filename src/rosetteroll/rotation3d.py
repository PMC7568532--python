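"""3D angular-velocity reconstruction from quasi-2D velocity fields.

A rotating sphere imaged near its surface produces an in-plane velocity
field that differs from a pure 2D rigid rotation because the visible
surface is curved: texture at in-plane radius ``rho`` sits at depth
``z(rho) = z_c - sqrt(R^2 - rho^2)`` (lower hemisphere for an inverted
microscope).  The finite focal depth weights each sample by its distance
to the focal plane, and this z-variation is what makes the in-plane
angular-velocity components identifiable from a single 2D field.

The module provides a minimal normalized-cross-correlation PIV front end,
the weighted linear least-squares rigid-rotation fit, and a
calibration-table axial position estimator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .trajectory import Trajectory

__all__ = [
    "VelocityField",
    "RigidRotationFit",
    "AxialCalibration",
    "DegenerateGeometryError",
    "piv_block_match",
    "fit_rigid_rotation",
    "estimate_axial_position",
    "reconstruct_track_3d",
]


class DegenerateGeometryError(RuntimeError):
    """Raised when velocity-field geometry cannot identify all components."""


@dataclass
class VelocityField:
    """Gridded in-plane velocity samples near the focal plane.

    Positions in um, velocities in um/s, weights in [0, 1] from the focal
    kernel; ``valid`` masks vectors that passed quality tests; ``empty``
    flags a focal plane that missed the object entirely.
    """

    x: np.ndarray
    y: np.ndarray
    vx: np.ndarray
    vy: np.ndarray
    weights: np.ndarray
    focal_plane_z: float
    focal_depth: float
    valid: np.ndarray
    empty: bool = False

    def __post_init__(self) -> None:
        n = len(self.x)
        for name in ("y", "vx", "vy", "weights", "valid"):
            if len(getattr(self, name)) != n:
                raise ValueError(f"field array {name!r} length mismatch")
        if n and (self.weights.min() < 0 or self.weights.max() > 1):
            raise ValueError("weights must lie in [0, 1]")

    @property
    def n_valid(self) -> int:
        return int(np.sum(self.valid))


@dataclass(frozen=True)
class RigidRotationFit:
    """Weighted LS fit of ``v = U + omega x (r - c)`` on a spherical surface."""

    omega: np.ndarray
    center: np.ndarray
    center_velocity: np.ndarray
    residual_rms: float
    condition: float

    @property
    def omega_inplane(self) -> float:
        """In-plane rotation speed ``omega_{x-y} = sqrt(wx^2 + wy^2)``."""
        return float(np.hypot(self.omega[0], self.omega[1]))


def piv_block_match(
    frame_a: np.ndarray,
    frame_b: np.ndarray,
    window: int = 16,
    overlap: float = 0.5,
    dt: float = 1.0,
    pixel_size: float = 1.0,
    peak_ratio_min: float = 1.2,
    focal_plane_z: float = 0.0,
    focal_depth: float = np.inf,
) -> VelocityField:
    """Normalized cross-correlation PIV between two frames.

    Each interrogation window of ``frame_a`` is correlated against the
    same-position window of ``frame_b`` (FFT correlation of zero-mean
    windows); the displacement is the correlation peak with a 3-point
    Gaussian sub-pixel refinement.  Vectors whose primary-to-secondary
    peak ratio falls below ``peak_ratio_min``, and blank windows, are
    masked invalid rather than treated as errors.
    """
    a = np.asarray(frame_a, dtype=float)
    b = np.asarray(frame_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("frames must share a shape")
    if window < 8:
        raise ValueError("window must be >= 8 px")
    step = max(1, int(round(window * (1.0 - overlap))))
    H, W = a.shape
    xs, ys, vxs, vys, valid = [], [], [], [], []
    for iy in range(0, H - window + 1, step):
        for ix in range(0, W - window + 1, step):
            wa = a[iy : iy + window, ix : ix + window]
            wb = b[iy : iy + window, ix : ix + window]
            wa = wa - wa.mean()
            wb = wb - wb.mean()
            na, nb = np.linalg.norm(wa), np.linalg.norm(wb)
            cx = ix + window / 2.0 - 0.5
            cy = iy + window / 2.0 - 0.5
            if na < 1e-12 or nb < 1e-12:  # blank window
                xs.append(cx), ys.append(cy), vxs.append(0.0), vys.append(0.0)
                valid.append(False)
                continue
            n2 = 2 * window
            corr = np.fft.irfft2(
                np.fft.rfft2(wb, (n2, n2)) * np.conj(np.fft.rfft2(wa, (n2, n2)))
            )
            corr = np.fft.fftshift(corr)[window // 2 : 3 * window // 2, window // 2 : 3 * window // 2]
            corr /= na * nb
            # remove the triangular bias of the padded correlation: rescale
            # each lag by the fraction of overlapping pixels
            lag = np.arange(window) - window // 2
            overlap_frac = np.outer(window - np.abs(lag), window - np.abs(lag)) / window**2
            corr /= np.maximum(overlap_frac, 0.25)  # cap amplification at 4x
            # quarter-window rule: only displacements up to w/4 are trusted
            search = np.full_like(corr, -np.inf)
            q = window // 4
            lo, hi = window // 2 - q, window // 2 + q + 1
            search[lo:hi, lo:hi] = corr[lo:hi, lo:hi]
            py, px = np.unravel_index(np.argmax(search), search.shape)
            peak = corr[py, px]
            # peak-ratio quality test against the best peak outside a 3x3 zone
            masked = search.copy()
            masked[max(py - 1, 0) : py + 2, max(px - 1, 0) : px + 2] = -np.inf
            second = masked.max()
            ok = second <= 0 or peak / max(second, 1e-12) >= peak_ratio_min
            dx = px - window // 2
            dy = py - window // 2
            # 3-point Gaussian sub-pixel interpolation per axis; falls back
            # to parabolic when a neighbour is non-positive
            def _subpix(cm, c0, cp):
                if cm > 0 and c0 > 0 and cp > 0:
                    lm, l0, lp = np.log(cm), np.log(c0), np.log(cp)
                else:
                    lm, l0, lp = cm, c0, cp
                denom = 2.0 * (lm + lp - 2.0 * l0)
                if abs(denom) < 1e-300:
                    return 0.0
                return float(np.clip((lm - lp) / denom, -1.0, 1.0))

            if 0 < px < corr.shape[1] - 1:
                dx += _subpix(corr[py, px - 1], peak, corr[py, px + 1])
            if 0 < py < corr.shape[0] - 1:
                dy += _subpix(corr[py - 1, px], peak, corr[py + 1, px])
            xs.append(cx), ys.append(cy)
            vxs.append(dx * pixel_size / dt)
            vys.append(dy * pixel_size / dt)
            valid.append(bool(ok))
    n = len(xs)
    return VelocityField(
        x=np.array(xs) * pixel_size,
        y=np.array(ys) * pixel_size,
        vx=np.array(vxs),
        vy=np.array(vys),
        weights=np.ones(n),
        focal_plane_z=focal_plane_z,
        focal_depth=focal_depth,
        valid=np.array(valid, dtype=bool),
        empty=n == 0,
    )


def fit_rigid_rotation(
    field: VelocityField,
    radius: float,
    center: np.ndarray,
    hemisphere: str = "lower",
    condition_max: float = 1e6,
    footprint: float | None = None,
    min_coverage: float = 0.6,
) -> RigidRotationFit:
    """Angular velocity and center velocity from a weighted linear LS fit.

    The model for each sample at (x, y) on the visible spherical surface
    (depth from the sphere equation) is::

        vx = Ux + wy * dz - wz * dy
        vy = Uy + wz * dx - wx * dz

    Unknowns ``(Ux, Uy, wx, wy, wz)``; the sphere center is fixed (it is
    measured independently from the filtered image centroid, and freeing
    it makes the design nearly collinear).  Weights are the focal-kernel
    weights times the validity mask.

    PIV vectors are window averages, so for fields produced by block
    matching pass ``footprint`` (the interrogation-window size in um):
    because the model is linear in position, the window-averaged velocity
    equals the model at the window-averaged ``(x, y, dz)`` over the part
    of the footprint inside the projected disk, which this option
    computes (weighted by the focal kernel when the field carries a
    finite focal depth).  Windows covering less than ``min_coverage`` of
    their footprint are dropped as rim-contaminated.

    Raises :class:`DegenerateGeometryError` when the design is effectively
    rank-deficient — e.g. all samples on one z shell, where ``wx, wy`` are
    indistinguishable from the translation.
    """
    center = np.asarray(center, dtype=float)
    m = field.valid & (field.weights > 0)
    if footprint is None:
        x = field.x[m] - center[0]
        y = field.y[m] - center[1]
        rho2 = x**2 + y**2
        if np.any(rho2 > radius**2 * (1 + 1e-9)):
            raise ValueError("field samples outside the projected sphere")
        dz_mag = np.sqrt(np.maximum(radius**2 - rho2, 0.0))
        dz = -dz_mag if hemisphere == "lower" else dz_mag
        w = field.weights[m]
    else:
        half = footprint / 2.0
        off = np.linspace(-half, half, 7)
        OX, OY = np.meshgrid(off, off)
        xs, ys, dzs, ws, keep_idx = [], [], [], [], []
        for i in np.flatnonzero(m):
            gx = field.x[i] + OX.ravel() - center[0]
            gy = field.y[i] + OY.ravel() - center[1]
            r2 = gx**2 + gy**2
            inside = r2 < radius**2
            cov = inside.mean()
            if cov < min_coverage:
                continue
            zz = -np.sqrt(radius**2 - r2[inside])
            if hemisphere == "upper":
                zz = -zz
            # projected texture density on a sphere scales as R/|dz|; the
            # correlation peak follows the texture, so weight accordingly
            wt = radius / np.maximum(np.abs(zz), 0.05 * radius)
            if np.isfinite(field.focal_depth):
                zlab = center[2] + zz
                wt = wt * np.exp(
                    -((zlab - field.focal_plane_z) ** 2) / (2 * field.focal_depth**2)
                )
            tot = wt.sum()
            xs.append(float((gx[inside] * wt).sum() / tot))
            ys.append(float((gy[inside] * wt).sum() / tot))
            dzs.append(float((zz * wt).sum() / tot))
            ws.append(field.weights[i])
            keep_idx.append(i)
        if len(keep_idx) < 6:
            raise ValueError("need at least 6 valid vectors for a rigid-rotation fit")
        m = np.zeros(len(field.x), dtype=bool)
        m[keep_idx] = True
        x = np.array(xs)
        y = np.array(ys)
        dz = np.array(dzs)
        w = np.array(ws)
    if m.sum() < 6:
        raise ValueError("need at least 6 valid vectors for a rigid-rotation fit")

    n = int(m.sum())
    A = np.zeros((2 * n, 5))
    rhs = np.empty(2 * n)
    # vx rows: Ux + wy dz - wz y
    A[:n, 0] = 1.0
    A[:n, 3] = dz
    A[:n, 4] = -y
    rhs[:n] = field.vx[m]
    # vy rows: Uy + wz x - wx dz
    A[n:, 1] = 1.0
    A[n:, 2] = -dz
    A[n:, 4] = x
    rhs[n:] = field.vy[m]
    ww = np.sqrt(np.concatenate([w, w]))
    Aw = A * ww[:, None]
    bw = rhs * ww
    # column scaling for an honest condition diagnostic
    scale = np.linalg.norm(Aw, axis=0)
    scale[scale == 0] = 1.0
    sol, _, rank, sv = np.linalg.lstsq(Aw / scale, bw, rcond=None)
    cond = float(sv[0] / sv[-1]) if sv[-1] > 0 else np.inf
    if rank < 5 or cond > condition_max:
        raise DegenerateGeometryError(
            "in-plane rotation components (wx, wy) are not identifiable from "
            f"this field geometry (condition {cond:.2e}); vary sampling in z "
            "or supply focal-kernel weights"
        )
    sol = sol / scale
    resid = Aw @ sol - bw
    rms = float(np.sqrt(np.sum(resid**2) / np.sum(ww**2)))
    U = np.array([sol[0], sol[1], 0.0])
    omega = np.array([sol[2], sol[3], sol[4]])
    return RigidRotationFit(
        omega=omega, center=center, center_velocity=U, residual_rms=rms, condition=cond
    )


def fit_rotation_sequence(
    frames: np.ndarray,
    dt: float,
    pixel_size: float,
    radius: float,
    center: np.ndarray,
    focal_plane_z: float,
    focal_depth: float,
    window: int = 16,
    overlap: float = 0.75,
    rho_max: float = 0.8,
) -> tuple[np.ndarray, list[RigidRotationFit]]:
    """Mean angular velocity of a textured sphere from a frame sequence.

    Runs PIV on every consecutive pair, fits the rigid-rotation model to
    each field (footprint-aware, restricted to the faithful inner region
    ``rho < rho_max * R`` where the projected pattern tracks the surface)
    and averages the per-pair estimates; single-pair in-plane components
    are noisy because their signal is the small depth variation across
    the disk, so the averaging over pairs is what delivers useful
    accuracy.  Returns the mean omega and the per-pair fits.
    """
    center = np.asarray(center, dtype=float)
    fits = []
    for k in range(len(frames) - 1):
        vf = piv_block_match(
            frames[k].astype(float),
            frames[k + 1].astype(float),
            window=window,
            overlap=overlap,
            dt=dt,
            pixel_size=pixel_size,
            focal_plane_z=focal_plane_z,
            focal_depth=focal_depth,
        )
        rho = np.hypot(vf.x - center[0], vf.y - center[1])
        vf.valid &= rho < rho_max * radius
        try:
            fits.append(fit_rigid_rotation(vf, radius, center, footprint=window * pixel_size))
        except (ValueError, DegenerateGeometryError):
            continue
    if not fits:
        raise ValueError("no frame pair produced a usable rotation fit")
    omega = np.mean([f.omega for f in fits], axis=0)
    return omega, fits


@dataclass(frozen=True)
class AxialCalibration:
    """Monotone mapping from a scalar focus metric to axial offset (um)."""

    metric_values: np.ndarray
    z_offsets: np.ndarray

    def __post_init__(self) -> None:
        mv = np.asarray(self.metric_values, float)
        z = np.asarray(self.z_offsets, float)
        if len(mv) != len(z) or len(mv) < 2:
            raise ValueError("calibration needs >= 2 (metric, z) pairs")
        d = np.diff(mv)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("focus metric must be strictly monotone in z")

    def z_from_metric(self, value: float) -> float:
        mv = self.metric_values
        z = self.z_offsets
        if mv[0] > mv[-1]:
            mv, z = mv[::-1], z[::-1]
        if not mv[0] <= value <= mv[-1]:
            raise ValueError(
                f"focus metric {value:.4g} outside calibrated range [{mv[0]:.4g}, {mv[-1]:.4g}]"
            )
        return float(np.interp(value, mv, z))


def focus_metric(image: np.ndarray, low_sigma: float = 1.0, high_sigma: float = 8.0) -> float:
    """Variance of the band-pass (difference-of-Gaussians) filtered image.

    Any strictly monotone function of defocus works as a focus metric once
    calibrated; band-passed variance is robust to uniform background.
    """
    img = np.asarray(image, dtype=float)
    band = ndimage.gaussian_filter(img, low_sigma) - ndimage.gaussian_filter(img, high_sigma)
    return float(band.var())


def estimate_axial_position(
    image: np.ndarray,
    calibration: AxialCalibration,
    low_sigma: float = 1.0,
    high_sigma: float = 8.0,
    threshold_quantile: float = 0.9,
) -> tuple[float, np.ndarray]:
    """Axial offset and 2D centroid of a single blurred object.

    The image is band-pass filtered so the object appears as one simply
    connected blob; the 2D position is the intensity centroid of the
    thresholded blob (pixel units), and z comes from the calibrated focus
    metric.
    """
    img = np.asarray(image, dtype=float)
    z = calibration.z_from_metric(focus_metric(img, low_sigma, high_sigma))
    smooth = ndimage.gaussian_filter(img, low_sigma)
    thr = np.quantile(smooth, threshold_quantile)
    mask = smooth >= thr
    if not mask.any():
        raise ValueError("no object above threshold")
    cy, cx = ndimage.center_of_mass(smooth * mask)
    return z, np.array([cx, cy])


def reconstruct_track_3d(
    frame_times: np.ndarray,
    image_offsets: np.ndarray,
    stage_times: np.ndarray,
    stage_positions: np.ndarray,
    z_estimates: np.ndarray,
    max_gap: int = 3,
) -> Trajectory:
    """Lab-frame 3D track = stage position + in-image offset + axial estimate.

    Stage samples are interpolated onto frame times; interior gaps of up
    to ``max_gap`` frames are bridged by interpolation, longer gaps raise
    (callers should split the track there).
    """
    ft = np.asarray(frame_times, float)
    off = np.asarray(image_offsets, float)
    st = np.asarray(stage_times, float)
    sp = np.asarray(stage_positions, float)
    if off.shape != (len(ft), 2):
        raise ValueError("image_offsets must be (n_frames, 2)")
    if sp.shape[0] != len(st):
        raise ValueError("stage log shape mismatch")
    inside = (ft >= st[0]) & (ft <= st[-1])
    if not inside.all():
        run = np.flatnonzero(~inside)
        if len(run) > max_gap:
            raise ValueError(
                f"{len(run)} frames outside the stage log exceed the {max_gap}-frame gap limit; split the track"
            )
        warnings.warn(f"extrapolating stage position over {len(run)} frames", stacklevel=2)
    stage_xyz = np.column_stack([np.interp(ft, st, sp[:, k]) for k in range(sp.shape[1])])
    if stage_xyz.shape[1] == 2:
        stage_xyz = np.column_stack([stage_xyz, np.zeros(len(ft))])
    pos = stage_xyz.copy()
    pos[:, 0] += off[:, 0]
    pos[:, 1] += off[:, 1]
    pos[:, 2] += np.asarray(z_estimates, float)
    return Trajectory(times=ft, positions=pos, unit_id="reconstructed", kind="rosette")
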