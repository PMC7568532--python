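"""Motor-state inference: switch detection, chirality, angles, durations."""

import numpy as np
import pytest
from helpers import match_events

from rosetteroll.motor import (
    MotorSegment,
    SwitchEvent,
    assign_motor_state,
    detect_switches,
    duration_and_restoring_stats,
    fit_mixture,
    turning_angle,
)
from rosetteroll.synthetic import (
    DurationSpec,
    MotorTelegraph,
    RosetteParams,
    SwarmerParams,
    sample_motor_telegraph,
    simulate_rolling_rosette,
    simulate_swarmer,
)
from rosetteroll.trajectory import Trajectory


def _traj(xy, dt=0.05, **kw):
    pos = np.column_stack([xy, np.zeros(len(xy))])
    return Trajectory(times=np.arange(len(xy)) * dt, positions=pos, **kw)


def _arc(direction=1, speed=3.6, rate=0.5, n=200, dt=0.05):
    """Circular arc: direction=+1 turns CCW, -1 CW."""
    t = np.arange(n) * dt
    heading = direction * rate * t
    v = speed * np.column_stack([np.cos(heading), np.sin(heading)])
    return np.vstack([np.zeros(2), np.cumsum(v[:-1] * dt, axis=0)])


# ---------------------------------------------------------------------------
# switch detection
# ---------------------------------------------------------------------------


def test_straight_track_has_no_switches():
    xy = np.column_stack([3.6 * np.arange(200) * 0.05, np.zeros(200)])
    events, segments = detect_switches(_traj(xy))
    assert events == []
    assert len(segments) == 1


def test_generator_switches_detected_within_two_frames():
    tel = MotorTelegraph(np.array([3.0, 5.5, 9.2]), "CW", total_time=12.0)
    p = RosetteParams(radius=4.0, omega=1.0, q_true=0.9)
    out = simulate_rolling_rosette(p, tel, None, 12.0, 0.05, 5)
    events, _ = detect_switches(out["trajectory"])
    det = np.array([e.time for e in events])
    assert len(det) == 3
    assert np.abs(det - tel.switch_times).max() <= 2 * 0.05 + 1e-9


def test_noiseless_track_switch_count_exact():
    tel = MotorTelegraph(np.array([3.0, 5.5, 9.2]), "CW", total_time=12.0)
    p = RosetteParams(radius=4.0, omega=1.0, q_true=0.9)
    out = simulate_rolling_rosette(
        p, tel, None, 12.0, 0.05, 5, noise_xy=0.0, axis_diffusivity=0.0
    )
    events, _ = detect_switches(out["trajectory"])
    assert len(events) == len(tel.switch_times)


def test_switch_recall_precision_at_default_noise():
    """Resolvable (lognormal) switching, default noise: recall & precision >= 0.95."""
    p = RosetteParams(radius=4.0, omega=1.0, q_true=0.9)
    tp = fp = fn = 0
    for i in range(10):
        tel = sample_motor_telegraph(
            DurationSpec("lognormal", mode=1.0, shape=0.6), 60.0, 50 + i
        )
        out = simulate_rolling_rosette(p, tel, None, 60.0, 0.05, 150 + i)
        events, _ = detect_switches(out["trajectory"])
        det = np.array([e.time for e in events])
        a, b, c = match_events(det, tel.switch_times, tol=0.3)
        tp, fp, fn = tp + a, fp + b, fn + c
    assert tp / (tp + fn) >= 0.95
    assert tp / (tp + fp) >= 0.95


def test_swarmer_switch_directions_alternate():
    tel = MotorTelegraph(np.array([1.0, 2.0, 3.0, 4.0]), "CW", total_time=5.0)
    p = SwarmerParams(speed=45.0, flick_jitter=0.0, rotational_diffusivity=0.0)
    out = simulate_swarmer(p, tel, 5.0, 0.01, 3)
    events, _ = detect_switches(out["trajectory"], window=0.1)
    dirs = [e.direction for e in events]
    assert dirs == ["CW->CCW", "CCW->CW", "CW->CCW", "CCW->CW"]


# ---------------------------------------------------------------------------
# motor-state assignment (chirality rule)
# ---------------------------------------------------------------------------


def test_ccw_arc_implies_cw_motor():
    t = _traj(_arc(direction=+1))
    seg = assign_motor_state(t, 0.0, t.times[-1])
    assert seg.state == "CW"
    assert seg.circulation == 1


def test_cw_arc_implies_ccw_motor():
    t = _traj(_arc(direction=-1))
    seg = assign_motor_state(t, 0.0, t.times[-1])
    assert seg.state == "CCW"
    assert seg.circulation == -1


def test_straight_segment_undetermined():
    xy = np.column_stack([3.6 * np.arange(200) * 0.05, np.zeros(200)])
    seg = assign_motor_state(_traj(xy), 0.0, 9.9)
    assert seg.state == "undetermined"


def test_chirality_flips_with_y_axis_mirror():
    """Mirroring the lab frame flips every circulation and motor label."""
    xy = _arc(direction=+1)
    s1 = assign_motor_state(_traj(xy), 0.0, 9.9)
    xy_m = xy * np.array([1.0, -1.0])
    s2 = assign_motor_state(_traj(xy_m), 0.0, 9.9)
    assert {s1.state, s2.state} == {"CW", "CCW"}
    assert s1.circulation == -s2.circulation


# ---------------------------------------------------------------------------
# turning angles
# ---------------------------------------------------------------------------


def test_perfect_backtrack_theta_pi():
    n = 100
    fwd = np.column_stack([3.6 * np.arange(n) * 0.05, np.zeros(n)])
    back = fwd[-1] - fwd[1 : n // 2]
    xy = np.vstack([fwd, back])
    t = _traj(xy)
    theta = turning_angle(t, SwitchEvent(time=n * 0.05, direction="unknown"))
    assert theta == pytest.approx(np.pi, abs=1e-6)


def test_right_angle_flick_theta_pi_over_2():
    n = 100
    leg1 = np.column_stack([np.arange(n) * 0.18, np.zeros(n)])
    leg2 = leg1[-1] + np.column_stack([np.zeros(n - 1), np.arange(1, n) * 0.18])
    t = _traj(np.vstack([leg1, leg2]))
    theta = turning_angle(t, SwitchEvent(time=n * 0.05, direction="unknown"))
    assert theta == pytest.approx(np.pi / 2, abs=1e-6)


def test_theta_invariant_under_rotation_and_translation():
    tel = MotorTelegraph(np.array([3.0]), "CW", total_time=6.0)
    p = RosetteParams(radius=4.0, omega=1.0, q_true=0.9)
    out = simulate_rolling_rosette(p, tel, None, 6.0, 0.05, 8)
    t = out["trajectory"]
    ev = SwitchEvent(time=3.0, direction="unknown")
    th0 = turning_angle(t, ev)
    phi = 1.1
    Rz = np.array([[np.cos(phi), -np.sin(phi)], [np.sin(phi), np.cos(phi)]])
    xy = t.xy() @ Rz.T + np.array([17.0, -4.0])
    th1 = turning_angle(_traj(xy), ev)
    assert th1 == pytest.approx(th0, abs=1e-9)


def test_rolling_ensemble_theta_mode_near_pi(rosette_ensemble):
    thetas = []
    for out in rosette_ensemble:
        events, _ = detect_switches(out["trajectory"])
        thetas.extend(e.theta for e in events if np.isfinite(e.theta))
    thetas = np.array(thetas)
    assert len(thetas) > 100
    hist, edges = np.histogram(thetas, bins=np.linspace(0, np.pi, 16))
    mode = 0.5 * (edges[np.argmax(hist)] + edges[np.argmax(hist) + 1])
    assert abs(mode - np.pi) < 0.2


# ---------------------------------------------------------------------------
# durations and restoring times
# ---------------------------------------------------------------------------


def _segments_from_telegraph(tel, total):
    return [
        MotorSegment(state, a, b, mean_curvature=0.1 if state == "CW" else -0.1)
        for a, b, state in tel.intervals(total)
    ]


def test_fixed_durations_restoring_exactly_two_seconds():
    tel = sample_motor_telegraph(DurationSpec("fixed", value=1.0), 10.0, 0)
    stats = duration_and_restoring_stats(_segments_from_telegraph(tel, 10.0))
    assert np.allclose(stats.restoring, 2.0)


def test_exponential_restoring_mean_is_two_tau():
    """Sum of consecutive exp(1) durations ~ Gamma(2, 1): mean 2 s within 2%."""
    tel = sample_motor_telegraph(DurationSpec("exponential", mean=1.0), 20000.0, 9)
    stats = duration_and_restoring_stats(_segments_from_telegraph(tel, 20000.0))
    assert len(stats.restoring) > 10_000
    assert stats.restoring.mean() == pytest.approx(2.0, rel=0.02)


def test_asymmetric_state_means_recovered():
    """CW mean 0.8 s / CCW mean 1.2 s recovered within 5%."""
    rng = np.random.default_rng(13)
    segs = []
    t = 0.0
    for k in range(20000):
        state = "CW" if k % 2 == 0 else "CCW"
        d = rng.exponential(0.8 if state == "CW" else 1.2)
        segs.append(MotorSegment(state, t, t + d))
        t += d
    stats = duration_and_restoring_stats(segs)
    assert stats.cw.mean() == pytest.approx(0.8, rel=0.05)
    assert stats.ccw.mean() == pytest.approx(1.2, rel=0.05)
    assert stats.restoring.mean() == pytest.approx(2.0, rel=0.05)


def test_same_state_neighbours_flagged_not_merged():
    segs = [
        MotorSegment("CW", 0.0, 1.0),
        MotorSegment("CW", 1.0, 2.0),
        MotorSegment("CCW", 2.0, 3.0),
    ]
    stats = duration_and_restoring_stats(segs)
    assert stats.n_flagged == 1
    assert len(stats.restoring) == 1


# ---------------------------------------------------------------------------
# mixture fitting
# ---------------------------------------------------------------------------


def test_single_gaussian_recovered():
    rng = np.random.default_rng(21)
    x = rng.normal(2.0, 0.5, 10_000)
    fit = fit_mixture(x, "gaussian", k=1, seed=0)
    assert fit.params[0, 0] == pytest.approx(2.0, rel=0.02)
    assert fit.params[0, 1] == pytest.approx(0.5, rel=0.02)


def test_exponential_mixture_rates_recovered():
    rng = np.random.default_rng(22)
    x = np.concatenate([rng.exponential(1.0, 10_000), rng.exponential(5.0, 10_000)])
    fit = fit_mixture(x, "exponential", k=2, seed=0)
    assert fit.params[0] == pytest.approx(1.0, rel=0.10)
    assert fit.params[1] == pytest.approx(5.0, rel=0.10)
    assert fit.weights[0] == pytest.approx(0.5, abs=0.07)


def test_degenerate_equal_samples_do_not_crash():
    x = np.full(100, 1.3)
    fit = fit_mixture(x, "gaussian", k=1, seed=0)
    assert fit.params[0, 0] == pytest.approx(1.3)


def test_mixture_deterministic_given_seed():
    rng = np.random.default_rng(23)
    x = np.concatenate([rng.exponential(1.0, 500), rng.exponential(4.0, 500)])
    f1 = fit_mixture(x, "exponential", k=2, seed=3)
    f2 = fit_mixture(x, "exponential", k=2, seed=3)
    assert np.array_equal(f1.params, f2.params)


def test_reflected_fit_keeps_components_in_range():
    rng = np.random.default_rng(24)
    x = np.clip(rng.normal(np.pi, 0.3, 5000), 0, np.pi)
    fit = fit_mixture(x, "gaussian", k=2, seed=0, reflect=(0.0, np.pi))
    assert np.all(fit.params[:, 0] >= -1e-9)
    assert np.all(fit.params[:, 0] <= np.pi + 1e-9)
    assert fit.weights.sum() == pytest.approx(1.0)
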