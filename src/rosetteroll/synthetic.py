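"""Synthetic data generators with known ground truth.

Every input the analysis pipeline consumes can be generated here:
telegraph motor-state processes, rolling-rosette and swarmer trajectories,
projected surface velocity fields, and textured image-frame pairs.  Each
generator returns its latent variables (states, angular velocities, switch
times) so that downstream estimators can be tested for parameter recovery.

The rosette generator encodes the rolling kinematics observed near a
wall: the rotation axis lies in the lab x-y plane, the translation is
perpendicular to it with speed ``Q * omega * R`` (Q = 1 is perfect no-slip
rolling), and a flagellar-motor reversal flips both the rotation and the
translation, producing a turning angle of pi before noise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .trajectory import Trajectory

__all__ = [
    "DurationSpec",
    "FluidParams",
    "RosetteParams",
    "SwarmerParams",
    "MotorTelegraph",
    "sample_motor_telegraph",
    "simulate_rolling_rosette",
    "simulate_swarmer",
    "project_surface_velocity_field",
    "render_texture_frames",
]

_BOLTZMANN = 1.380649e-23  # J/K


@dataclass(frozen=True)
class DurationSpec:
    """Distribution of motor-state durations.

    Families: ``exponential`` (param ``mean``, s), ``lognormal`` (params
    ``mode`` in s and log-space ``shape``), ``fixed`` (param ``value``, s).
    """

    family: str
    mean: float | None = None
    mode: float | None = None
    shape: float | None = None
    value: float | None = None

    def __post_init__(self) -> None:
        if self.family == "exponential":
            if self.mean is None or self.mean <= 0:
                raise ValueError("exponential family needs mean > 0")
        elif self.family == "lognormal":
            if self.mode is None or self.mode <= 0 or self.shape is None or self.shape <= 0:
                raise ValueError("lognormal family needs mode > 0 and shape > 0")
        elif self.family == "fixed":
            if self.value is None or self.value <= 0:
                raise ValueError("fixed family needs value > 0")
        else:
            raise ValueError(f"unsupported duration family {self.family!r}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "exponential":
            return rng.exponential(self.mean, size)
        if self.family == "lognormal":
            mu = np.log(self.mode) + self.shape**2  # mode = exp(mu - shape^2)
            return rng.lognormal(mu, self.shape, size)
        return np.full(size, self.value)

    @property
    def expected_mean(self) -> float:
        if self.family == "exponential":
            return self.mean
        if self.family == "lognormal":
            mu = np.log(self.mode) + self.shape**2
            return float(np.exp(mu + self.shape**2 / 2.0))
        return self.value


@dataclass(frozen=True)
class FluidParams:
    """Suspending fluid: viscosity (Pa s) and temperature (K)."""

    viscosity: float = 1.0e-3
    temperature: float = 303.0

    def __post_init__(self) -> None:
        if self.viscosity <= 0:
            raise ValueError("viscosity must be positive")


def _unit(v) -> np.ndarray:
    v = np.asarray(v, float)
    if abs(np.linalg.norm(v) - 1.0) > 1e-9:
        raise ValueError("vector must be unit length")
    return v


@dataclass(frozen=True)
class RosetteParams:
    """Geometry and kinematic scales of a rosette aggregate.

    ``radius`` R (um) and ``gap`` d (um) set the wall proximity d/R;
    ``omega`` (rad/s) and ``q_true`` fix the rolling translation speed
    ``q_true * omega * R`` unless ``speed`` overrides it.  ``n_members``
    and ``eccentricity`` describe the aggregate shape (e = 0: sphere).
    """

    radius: float = 4.0
    eccentricity: float = 0.0
    n_members: int = 20
    gap: float = 0.8
    anchor_dir: tuple = (1.0, 0.0, 0.0)
    motor_axis: tuple = (1.0, 0.0, 0.0)
    speed: float | None = None
    omega: float = 1.0
    q_true: float = 0.9
    duration_spec: DurationSpec = field(default_factory=lambda: DurationSpec("exponential", mean=1.0))

    def __post_init__(self) -> None:
        if self.radius <= 0:
            raise ValueError("radius must be positive")
        if not 0.0 <= self.eccentricity < 1.0:
            raise ValueError("eccentricity must be in [0, 1)")
        if self.gap < 0:
            raise ValueError("gap must be non-negative")
        if not 0.0 <= self.q_true <= 1.0:
            raise ValueError("q_true must be in [0, 1]")
        _unit(self.anchor_dir)
        _unit(self.motor_axis)

    @property
    def height(self) -> float:
        """Center height above the wall, h = d + R."""
        return self.gap + self.radius

    @property
    def roll_speed(self) -> float:
        return self.speed if self.speed is not None else self.q_true * self.omega * self.radius


@dataclass(frozen=True)
class SwarmerParams:
    """Solitary swarmer-cell kinematics: run speed and reorientation angles."""

    speed: float = 45.0
    flick_angle: float = np.pi / 2.0
    flick_jitter: float = 0.3
    reverse_jitter: float = 0.0
    duration_spec: DurationSpec = field(default_factory=lambda: DurationSpec("exponential", mean=1.0))
    rotational_diffusivity: float = 0.05

    def __post_init__(self) -> None:
        if self.speed <= 0:
            raise ValueError("speed must be positive")
        if self.rotational_diffusivity < 0:
            raise ValueError("rotational diffusivity must be non-negative")


@dataclass(frozen=True)
class MotorTelegraph:
    """Alternating CW/CCW motor process: switch times and initial state."""

    switch_times: np.ndarray
    initial_state: str = "CW"
    total_time: float | None = None

    def __post_init__(self) -> None:
        st = np.asarray(self.switch_times, float)
        object.__setattr__(self, "switch_times", st)
        if st.ndim != 1:
            raise ValueError("switch_times must be 1D")
        if len(st) > 1 and np.any(np.diff(st) <= 0):
            raise ValueError("switch times must be strictly increasing")
        if self.initial_state not in ("CW", "CCW"):
            raise ValueError("initial_state must be CW or CCW")

    def state_at(self, t) -> str | np.ndarray:
        """Motor state at time(s) t (switch instants belong to the new state)."""
        n = np.searchsorted(self.switch_times, np.asarray(t, float), side="right")
        other = "CCW" if self.initial_state == "CW" else "CW"
        out = np.where(n % 2 == 0, self.initial_state, other)
        return out if out.ndim else str(out)

    def sign_at(self, t):
        """+1 in the initial state, -1 in the other."""
        n = np.searchsorted(self.switch_times, np.asarray(t, float), side="right")
        return 1.0 - 2.0 * (n % 2)

    def intervals(self, total_time: float | None = None) -> list[tuple[float, float, str]]:
        end = total_time if total_time is not None else self.total_time
        if end is None:
            raise ValueError("total_time unknown")
        edges = np.concatenate([[0.0], self.switch_times, [end]])
        out = []
        state = self.initial_state
        for a, b in zip(edges[:-1], edges[1:]):
            if b > a:
                out.append((float(a), float(b), state))
            state = "CCW" if state == "CW" else "CW"
        return out


def sample_motor_telegraph(
    duration_spec: DurationSpec,
    total_time: float,
    seed: int | np.random.Generator,
    initial_state: str = "CW",
) -> MotorTelegraph:
    """Draw alternating motor-state intervals covering [0, total_time]."""
    if total_time <= 0:
        raise ValueError("total_time must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    switches = []
    t = 0.0
    while True:
        d = float(duration_spec.sample(rng, 1)[0])
        t += d
        if t >= total_time:
            break
        switches.append(t)
    return MotorTelegraph(
        switch_times=np.array(switches), initial_state=initial_state, total_time=total_time
    )


def simulate_rolling_rosette(
    params: RosetteParams,
    telegraph: MotorTelegraph,
    fluid: FluidParams | None,
    total_time: float,
    dt: float,
    seed: int | np.random.Generator,
    noise_xy: float = 0.05,
    axis_diffusivity: float = 0.05,
    circulation_rate: float = 0.3,
    include_brownian: bool = False,
    free_space_beta: str = "uniform",
    unit_id: str = "rosette-0",
) -> dict:
    """Rolling-rosette trajectory with ground-truth rotation.

    The in-plane rotation-axis angle ``alpha`` performs a slow random walk
    (``axis_diffusivity`` rad^2/s) superposed on a chirality drift:
    flagellar propulsion near the wall curls the path, CCW for a CW motor
    and CW for a CCW motor, so ``alpha`` drifts at ``+circulation_rate``
    (rad/s) in the CW state and the opposite in CCW.  The signed axis
    flips at every motor switch, flipping the perpendicular translation
    with it, so the ground-truth turning angle at each switch is exactly
    pi before noise.  Positional noise is additive per frame
    (measurement-like, does not accumulate).  Far from the wall
    (``d/R > 2``) the rolling constraint is released: the angle from axis
    to translation is drawn once per track from ``free_space_beta``
    ("uniform" over [0, 2pi) or "rolling" to keep 3pi/2).

    Returns a dict with the Trajectory and latent series (``omega`` vectors,
    ``axis_angle``, per-frame ``states``, the telegraph itself).
    """
    if dt <= 0 or total_time <= 0:
        raise ValueError("dt and total_time must be positive")
    if params.gap < 0:
        raise ValueError("gap must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(total_time / dt)) + 1
    times = np.arange(n) * dt

    sgn = telegraph.sign_at(times)
    # CW motor state (sign +1 when initial_state == "CW") -> CCW circulation
    cw_sign = sgn if telegraph.initial_state == "CW" else -sgn
    alpha = np.empty(n)
    alpha[0] = rng.uniform(0.0, 2.0 * np.pi)
    steps = rng.normal(0.0, np.sqrt(2.0 * axis_diffusivity * dt), n - 1)
    steps = steps + circulation_rate * cw_sign[:-1] * dt
    alpha[1:] = alpha[0] + np.cumsum(steps)
    free_space = params.gap / params.radius > 2.0
    if free_space and free_space_beta == "uniform":
        beta_offset = rng.uniform(0.0, 2.0 * np.pi)
    else:
        beta_offset = 3.0 * np.pi / 2.0

    speed = params.roll_speed
    dir_angle = alpha + beta_offset
    vel = speed * np.column_stack([np.cos(dir_angle), np.sin(dir_angle)]) * sgn[:, None]
    pos_xy = np.zeros((n, 2))
    pos_xy[1:] = np.cumsum(0.5 * (vel[:-1] + vel[1:]) * dt, axis=0)

    z = np.full(n, params.height)
    positions = np.column_stack([pos_xy, z])
    if include_brownian and fluid is not None:
        d_trans = (
            _BOLTZMANN * fluid.temperature / (6.0 * np.pi * fluid.viscosity * params.radius * 1e-6)
        ) * 1e12  # um^2/s
        positions += np.vstack(
            [np.zeros(3), np.cumsum(rng.normal(0.0, np.sqrt(2 * d_trans * dt), (n - 1, 3)), axis=0)]
        )
    observed = positions + rng.normal(0.0, noise_xy, positions.shape)

    omega_vec = (
        params.omega
        * sgn[:, None]
        * np.column_stack([np.cos(alpha), np.sin(alpha), np.zeros(n)])
    )
    states = list(np.atleast_1d(telegraph.state_at(times)))
    traj = Trajectory(times=times, positions=observed, unit_id=unit_id, kind="rosette", states=states)
    return {
        "trajectory": traj,
        "clean_positions": positions,
        "omega": omega_vec,
        "axis_angle": alpha,
        "states": states,
        "telegraph": telegraph,
        "beta_true": 3.0 * np.pi / 2.0 if not free_space else beta_offset,
    }


def simulate_swarmer(
    params: SwarmerParams,
    telegraph: MotorTelegraph,
    total_time: float,
    dt: float,
    seed: int | np.random.Generator,
    noise_xy: float = 0.0,
    unit_id: str = "swarmer-0",
) -> dict:
    """Run-reverse-flick swarmer track.

    Heading reverses (pi) on a CW-to-CCW motor switch and flicks (default
    pi/2 with jitter, random side) on CCW-to-CW, mirroring the buckling
    reorientation of the flagellar hook.  Between switches the heading
    diffuses rotationally.
    """
    if dt <= 0 or total_time <= 0:
        raise ValueError("dt and total_time must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n = int(round(total_time / dt)) + 1
    times = np.arange(n) * dt

    heading = np.empty(n)
    heading[0] = rng.uniform(0.0, 2.0 * np.pi)
    diff_steps = rng.normal(0.0, np.sqrt(2.0 * params.rotational_diffusivity * dt), n - 1)
    switch_idx = np.searchsorted(times, telegraph.switch_times, side="left")
    turn = np.zeros(n)
    state = telegraph.initial_state
    for k, idx in enumerate(switch_idx):
        if idx >= n:
            break
        if state == "CW":  # CW -> CCW: reversal
            turn[idx] += np.pi + rng.normal(0.0, params.reverse_jitter)
        else:  # CCW -> CW: flick
            side = rng.choice([-1.0, 1.0])
            turn[idx] += side * (params.flick_angle + rng.normal(0.0, params.flick_jitter))
        state = "CCW" if state == "CW" else "CW"
    heading[1:] = heading[0] + np.cumsum(diff_steps + turn[1:])

    vel = params.speed * np.column_stack([np.cos(heading), np.sin(heading)])
    pos_xy = np.zeros((n, 2))
    pos_xy[1:] = np.cumsum(vel[:-1] * dt, axis=0)
    positions = np.column_stack([pos_xy, np.zeros(n)])
    if noise_xy > 0:
        positions = positions + rng.normal(0.0, noise_xy, positions.shape)
    states = list(np.atleast_1d(telegraph.state_at(times)))
    traj = Trajectory(times=times, positions=positions, unit_id=unit_id, kind="swarmer", states=states)
    return {"trajectory": traj, "heading": heading, "states": states, "telegraph": telegraph}


def project_surface_velocity_field(
    radius: float,
    center: np.ndarray,
    omega: np.ndarray,
    center_velocity: np.ndarray,
    focal_plane_z: float,
    focal_depth: float,
    grid_step: float = 0.25,
    hemisphere: str = "lower",
    noise: float = 0.0,
    rng: np.random.Generator | None = None,
):
    """In-plane velocity field of a rigid sphere surface near the focal plane.

    Each grid point (x, y) inside the projected disk maps to the visible
    surface point (the hemisphere nearer the objective; "lower" for an
    inverted microscope); the field is the in-plane part of
    ``v = U + omega x (r - c)`` there, weighted by a Gaussian focal kernel
    ``exp(-(z_s - z_f)^2 / (2 depth^2))``.

    Returns a :class:`rosetteroll.rotation3d.VelocityField`; if the focal
    plane misses the sphere the field is empty and flagged.
    """
    from .rotation3d import VelocityField

    center = np.asarray(center, float)
    omega = np.asarray(omega, float)
    U = np.asarray(center_velocity, float)
    if hemisphere not in ("lower", "upper"):
        raise ValueError("hemisphere must be 'lower' or 'upper'")
    empty = abs(focal_plane_z - center[2]) >= radius

    half = radius
    g = np.arange(-half, half + 0.5 * grid_step, grid_step)
    X, Y = np.meshgrid(center[0] + g, center[1] + g)
    rho2 = (X - center[0]) ** 2 + (Y - center[1]) ** 2
    inside = rho2 < radius**2 * (1 - 1e-12)
    x = X[inside]
    y = Y[inside]
    if empty:
        x = x[:0]
        y = y[:0]
    dz = np.sqrt(np.maximum(radius**2 - ((x - center[0]) ** 2 + (y - center[1]) ** 2), 0.0))
    zs = center[2] - dz if hemisphere == "lower" else center[2] + dz
    r = np.column_stack([x, y, zs]) - center
    v = U[None, :] + np.cross(np.broadcast_to(omega, r.shape), r)
    w = np.exp(-((zs - focal_plane_z) ** 2) / (2.0 * focal_depth**2))
    vx, vy = v[:, 0], v[:, 1]
    if noise > 0:
        if rng is None:
            rng = np.random.default_rng()
        scale = 1.0 + rng.normal(0.0, noise, vx.shape)
        vx = vx * scale
        vy = vy * (1.0 + rng.normal(0.0, noise, vy.shape))
    return VelocityField(
        x=x,
        y=y,
        vx=vx,
        vy=vy,
        weights=w,
        focal_plane_z=focal_plane_z,
        focal_depth=focal_depth,
        valid=np.ones(len(x), dtype=bool),
        empty=bool(empty),
    )


def sample_surface_markers(
    radius: float, n_markers: int, seed: int | np.random.Generator
) -> np.ndarray:
    """Uniform random points on the sphere surface (body frame)."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    v = rng.normal(size=(n_markers, 3))
    return radius * v / np.linalg.norm(v, axis=1, keepdims=True)


def render_texture_frames(
    centers: np.ndarray,
    rotations: np.ndarray,
    markers_body: np.ndarray,
    radius: float,
    pixel_size: float,
    image_shape: tuple[int, int],
    focal_plane_z: float,
    focal_depth: float,
    blob_sigma_px: float = 1.5,
    hemisphere: str = "lower",
    peak_intensity: float = 200.0,
) -> np.ndarray:
    """Render a sequence of 8-bit frames of surface markers on a rigid sphere.

    ``centers`` (T, 3) and ``rotations`` (T, 3, 3) give the sphere pose per
    frame; markers are Gaussian blobs whose intensity is attenuated by the
    focal kernel and whose visibility is restricted to the hemisphere
    nearer the objective.  Pixel (0, 0) center sits at the lab origin;
    positions map to pixels as ``x / pixel_size``.
    """
    if len(markers_body) < 20:
        raise ValueError("need at least 20 surface markers")
    T = len(centers)
    H, W = image_shape
    frames = np.zeros((T, H, W), dtype=np.uint8)
    yy, xx = np.mgrid[0:H, 0:W]
    for t in range(T):
        lab = centers[t] + markers_body @ rotations[t].T
        rel_z = lab[:, 2] - centers[t][2]
        visible = rel_z <= 0 if hemisphere == "lower" else rel_z >= 0
        img = np.zeros((H, W))
        for m in np.where(visible)[0]:
            px = lab[m, 0] / pixel_size
            py = lab[m, 1] / pixel_size
            wz = np.exp(-((lab[m, 2] - focal_plane_z) ** 2) / (2.0 * focal_depth**2))
            img += wz * np.exp(-((xx - px) ** 2 + (yy - py) ** 2) / (2.0 * blob_sigma_px**2))
        # fixed scale across frames (a focused isolated marker peaks at
        # peak_intensity) so frame-to-frame correlation reflects motion,
        # not renormalization; dense textures should lower the scale to
        # avoid saturation of overlapping blobs
        frames[t] = np.clip(img * peak_intensity, 0, 255).astype(np.uint8)
    return frames
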