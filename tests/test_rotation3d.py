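"""PIV front end, rigid-rotation fitting, axial calibration, 3D tracks."""

import numpy as np
import pytest
from scipy import ndimage
from scipy.spatial.transform import Rotation

from rosetteroll.rotation3d import (
    AxialCalibration,
    DegenerateGeometryError,
    VelocityField,
    estimate_axial_position,
    fit_rigid_rotation,
    fit_rotation_sequence,
    focus_metric,
    piv_block_match,
    reconstruct_track_3d,
)
from rosetteroll.synthetic import (
    project_surface_velocity_field,
    render_texture_frames,
    sample_surface_markers,
)

# ---------------------------------------------------------------------------
# PIV block matching
# ---------------------------------------------------------------------------


def _texture(seed=0, shape=(96, 96)):
    rng = np.random.default_rng(seed)
    return ndimage.gaussian_filter(rng.uniform(size=shape), 1.5)


def test_identical_frames_give_zero_field():
    a = _texture()
    vf = piv_block_match(a, a, window=16)
    assert np.allclose(vf.vx[vf.valid], 0.0, atol=1e-9)
    assert np.allclose(vf.vy[vf.valid], 0.0, atol=1e-9)


def test_integer_shift_recovered():
    a = _texture(1, (128, 128))
    b = np.roll(a, 3, axis=1)
    vf = piv_block_match(a, b, window=32, overlap=0.5)
    inner = vf.valid
    assert np.mean(vf.vx[inner]) == pytest.approx(3.0, abs=0.05)
    assert np.abs(vf.vx[inner] - 3.0).max() < 0.3
    assert np.abs(vf.vy[inner]).max() < 0.3


def test_blank_windows_masked_not_raised():
    a = np.zeros((64, 64))
    vf = piv_block_match(a, a, window=16)
    assert not vf.valid.any()


def test_rendered_spin_matches_projected_field():
    """PIV on rendered frames tracks the projected surface field.

    Gentle spin (0.025 rad/frame, 32-px windows): < 0.2 px/frame RMS.
    Fast spin (0.1 rad/frame, 16-px windows): shear across the window
    dominates; < 0.4 px/frame RMS.
    """
    from scipy.interpolate import griddata

    R, px, n_px, dt = 4.0, 0.1, 96, 0.05
    center = np.array([n_px * px / 2, n_px * px / 2, R])
    fpz = center[2] - R * 0.5
    markers = sample_surface_markers(R, 2000, 1)
    for omz, window, tol in [(0.5, 32, 0.2), (2.0, 16, 0.4)]:
        om = np.array([0.0, 0.0, omz])
        rot1 = Rotation.from_rotvec(om * dt).as_matrix()
        frames = render_texture_frames(
            np.array([center] * 2), np.array([np.eye(3), rot1]), markers, R,
            pixel_size=px, image_shape=(n_px, n_px), focal_plane_z=fpz,
            focal_depth=2.5, blob_sigma_px=1.2, peak_intensity=60,
        )
        vf = piv_block_match(
            frames[0].astype(float), frames[1].astype(float),
            window=window, overlap=0.75, dt=dt, pixel_size=px,
        )
        truth = project_surface_velocity_field(R, center, om, np.zeros(3), fpz, 2.5, grid_step=0.1)
        vx_t = griddata((truth.x, truth.y), truth.vx, (vf.x, vf.y), method="linear")
        vy_t = griddata((truth.x, truth.y), truth.vy, (vf.x, vf.y), method="linear")
        rho = np.hypot(vf.x - center[0], vf.y - center[1])
        m = vf.valid & np.isfinite(vx_t) & (rho < 0.8 * R)
        rms = np.sqrt(np.mean((vf.vx - vx_t)[m] ** 2 + (vf.vy - vy_t)[m] ** 2))
        assert rms * dt / px < tol


# ---------------------------------------------------------------------------
# rigid-rotation fit
# ---------------------------------------------------------------------------


def _field(omega, U=np.zeros(3), R=4.0, c=np.array([0.0, 0.0, 5.0]), noise=0.0, rng=None):
    return project_surface_velocity_field(
        R, c, np.asarray(omega, float), np.asarray(U, float), c[2] - R / 2, 1.0,
        noise=noise, rng=rng,
    )


def test_pure_translation_recovered_with_zero_omega():
    f = _field([0, 0, 0], U=[1.2, -0.4, 0.0])
    fit = fit_rigid_rotation(f, 4.0, np.array([0.0, 0.0, 5.0]))
    assert np.allclose(fit.omega, 0.0, atol=1e-12)
    assert np.allclose(fit.center_velocity[:2], [1.2, -0.4], atol=1e-12)


def test_noiseless_field_recovers_omega_to_machine_precision():
    om = np.array([0.3, -0.2, 0.9])
    f = _field(om, U=[0.5, 0.1, 0.0])
    fit = fit_rigid_rotation(f, 4.0, np.array([0.0, 0.0, 5.0]))
    assert np.allclose(fit.omega, om, atol=1e-12)
    assert fit.residual_rms < 1e-12
    assert fit.omega_inplane == pytest.approx(np.hypot(0.3, -0.2), abs=1e-12)


def test_noisy_recovery_within_tolerance_over_repeats():
    """5% multiplicative noise: |w_hat - w| < 0.05 rad/s in 95% of 500 runs."""
    om = np.array([0.3, -0.2, 0.9])
    hits = 0
    n_rep = 500
    for k in range(n_rep):
        rng = np.random.default_rng(1000 + k)
        f = _field(om, noise=0.05, rng=rng)
        fit = fit_rigid_rotation(f, 4.0, np.array([0.0, 0.0, 5.0]))
        if np.linalg.norm(fit.omega - om) < 0.05:
            hits += 1
    assert hits / n_rep >= 0.95


def test_equivariance_under_rotation_about_z():
    """Rotating the field by phi rotates (wx, wy) and U; wz is unchanged."""
    om = np.array([0.3, -0.2, 0.9])
    U = np.array([0.5, 0.1, 0.0])
    c = np.array([0.0, 0.0, 5.0])
    f = _field(om, U=U, c=c)
    phi = 0.7
    cph, sph = np.cos(phi), np.sin(phi)
    Rz = np.array([[cph, -sph], [sph, cph]])
    xy = np.column_stack([f.x, f.y]) @ Rz.T
    vv = np.column_stack([f.vx, f.vy]) @ Rz.T
    f_rot = VelocityField(
        x=xy[:, 0], y=xy[:, 1], vx=vv[:, 0], vy=vv[:, 1], weights=f.weights,
        focal_plane_z=f.focal_plane_z, focal_depth=f.focal_depth, valid=f.valid,
    )
    fit = fit_rigid_rotation(f_rot, 4.0, c)
    assert fit.omega[2] == pytest.approx(om[2], abs=1e-10)
    assert np.allclose(fit.omega[:2], Rz @ om[:2], atol=1e-10)
    assert np.allclose(fit.center_velocity[:2], Rz @ U[:2], atol=1e-10)


def test_single_z_shell_geometry_is_flagged_degenerate():
    """Samples on one ring share one depth: wx, wy collapse into U."""
    theta = np.linspace(0, 2 * np.pi, 40, endpoint=False)
    R, c = 4.0, np.array([0.0, 0.0, 5.0])
    rho = 2.0
    x, y = rho * np.cos(theta), rho * np.sin(theta)
    om = np.array([0.3, -0.2, 0.9])
    z = c[2] - np.sqrt(R**2 - rho**2)
    r = np.column_stack([x, y, z - c[2] + np.zeros_like(x)])
    r[:, 2] = z - c[2]
    v = np.cross(np.broadcast_to(om, r.shape), r)
    f = VelocityField(
        x=x, y=y, vx=v[:, 0], vy=v[:, 1], weights=np.ones_like(x),
        focal_plane_z=z, focal_depth=0.5, valid=np.ones_like(x, dtype=bool),
    )
    with pytest.raises(DegenerateGeometryError):
        fit_rigid_rotation(f, R, c, condition_max=1e4)


def test_end_to_end_sequence_recovers_omega_within_10_percent():
    """Frames -> PIV -> fit over a sequence: |w| in [0.5, 2] within 10%."""
    R, px, n_px, dt = 4.0, 0.1, 96, 0.05
    center = np.array([n_px * px / 2, n_px * px / 2, R])
    fpz = center[2] - R * 0.5
    markers = sample_surface_markers(R, 2000, 1)
    for om in (np.array([0.5, 0.0, 0.0]), np.array([0.3, -0.2, 0.9])):
        rots = np.array([Rotation.from_rotvec(om * dt * k).as_matrix() for k in range(31)])
        frames = render_texture_frames(
            np.repeat(center[None], 31, axis=0), rots, markers, R,
            pixel_size=px, image_shape=(n_px, n_px), focal_plane_z=fpz,
            focal_depth=2.5, blob_sigma_px=1.2, peak_intensity=60,
        )
        om_hat, fits = fit_rotation_sequence(
            frames, dt, px, R, center, fpz, 2.5, window=16, overlap=0.75
        )
        assert np.linalg.norm(om_hat - om) / np.linalg.norm(om) < 0.10
        assert len(fits) >= 25


# ---------------------------------------------------------------------------
# axial calibration and 3D track reconstruction
# ---------------------------------------------------------------------------


def _defocus_stack(z_values, seed=0):
    """Synthetic defocus series: blur grows monotonically with |z|."""
    rng = np.random.default_rng(seed)
    base = rng.uniform(size=(64, 64))
    return [ndimage.gaussian_filter(base, 1.0 + 0.8 * abs(z)) for z in z_values]


def test_calibrated_query_returns_calibrated_z_exactly():
    cal = AxialCalibration(metric_values=[1.0, 2.0, 4.0], z_offsets=[-1.0, 0.0, 1.0])
    assert cal.z_from_metric(2.0) == 0.0
    assert cal.z_from_metric(3.0) == 0.5  # midpoint of a linear segment
    with pytest.raises(ValueError):
        cal.z_from_metric(9.0)


def test_non_monotone_calibration_rejected():
    with pytest.raises(ValueError):
        AxialCalibration(metric_values=[1.0, 3.0, 2.0], z_offsets=[-1.0, 0.0, 1.0])


def test_defocus_series_z_error_below_calibration_step():
    z_cal = np.linspace(-2.0, 2.0, 9)  # 0.5-um steps; blur even in z ->
    z_cal = z_cal[z_cal <= 0]  # use the monotone branch
    stack = _defocus_stack(z_cal)
    cal = AxialCalibration(
        metric_values=[focus_metric(im) for im in stack], z_offsets=z_cal
    )
    z_query = np.array([-1.75, -1.2, -0.6])
    q_stack = _defocus_stack(z_query)
    errs = [abs(cal.z_from_metric(focus_metric(im)) - z) for im, z in zip(q_stack, z_query)]
    assert max(errs) < 0.5


def test_axial_estimate_centroid_of_blob():
    img = np.zeros((64, 64))
    img[40, 22] = 1.0
    img = ndimage.gaussian_filter(img, 3.0)
    cal = AxialCalibration(metric_values=[0.0, 1.0], z_offsets=[0.0, 1.0])
    z, cxy = estimate_axial_position(img, cal)
    assert cxy == pytest.approx([22.0, 40.0], abs=0.5)


def test_reconstruct_static_object_moving_stage():
    ft = np.arange(50) * 0.1
    stage = np.column_stack([np.sin(ft), np.cos(ft), 0.1 * ft])
    traj = reconstruct_track_3d(ft, np.zeros((50, 2)), ft, stage, np.zeros(50))
    assert np.allclose(traj.positions[:, :2], stage[:, :2])


def test_reconstruct_moving_object_static_stage():
    ft = np.arange(50) * 0.1
    off = np.column_stack([0.5 * ft, -0.2 * ft])
    traj = reconstruct_track_3d(ft, off, ft, np.zeros((50, 3)), np.zeros(50))
    assert np.allclose(traj.positions[:, :2], off)


def test_reconstruct_both_moving_matches_truth():
    rng = np.random.default_rng(5)
    ft = np.arange(100) * 0.05
    truth = np.column_stack([3.6 * ft, np.sin(ft), 5.0 + 0.2 * np.sin(2 * ft)])
    stage = truth + rng.normal(0, 0.02, truth.shape)  # stage follows object
    stage[:, 2] = 0.0
    offsets = truth[:, :2] - stage[:, :2]
    traj = reconstruct_track_3d(ft, offsets, ft, stage, truth[:, 2])
    err = np.linalg.norm(traj.positions[:, :2] - truth[:, :2], axis=1)
    assert np.sqrt(np.mean(err**2)) < 0.1
    assert np.allclose(traj.positions[:, 2], truth[:, 2])


def test_reconstruct_rejects_long_stage_gaps():
    ft = np.arange(50) * 0.1
    with pytest.raises(ValueError):
        reconstruct_track_3d(ft, np.zeros((50, 2)), ft[:40], np.zeros((40, 3)), np.zeros(50))
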