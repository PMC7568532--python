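"""Hydrodynamic models for rosette propulsion and rolling.

Four physical models live here:

* closed-form rotational drag of a spheroid and the torque-scaling argument
  comparing a rosette to a solitary swimmer;
* a first-kind boundary-integral solver for the mobility of a rigid sphere
  above a no-slip plane wall, which predicts the hydrodynamic slipping
  ratio ``Q(d/R)`` of a torque-driven sphere;
* a resistive-force-theory simulator of a sphere propelled by a rotating
  helical filament near the wall;
* a binomial model for the number of simultaneously active flagella on a
  rosette of cells dividing asynchronously.

Units: the boundary-integral and RFT solvers are scale-invariant and run
in units of the sphere radius; the drag formulas take SI inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import lu_factor, lu_solve
from scipy.spatial.transform import Rotation

from .stokes import SphereMesh, _image_correction, oseen_tensor, sphere_mesh
from .synthetic import MotorTelegraph

__all__ = [
    "SpheroidDrag",
    "spheroid_rotational_drag",
    "TorqueEstimate",
    "torque_ratio",
    "round_to_1sf",
    "WallMobility",
    "sphere_wall_grand_mobility",
    "wall_mobility_torque_driven_sphere",
    "FlagellatedSphereParams",
    "simulate_flagellated_sphere",
    "FlagellationModel",
    "flagellation_probability",
]


# ---------------------------------------------------------------------------
# Spheroid rotational drag and torque scaling
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SpheroidDrag:
    """Rotational drag of a prolate spheroid spinning about a minor axis.

    ``sigma`` is the torque per unit angular speed (N m s); ``xi`` is the
    eccentricity-dependent shape factor.
    """

    radius: float
    eccentricity: float
    viscosity: float
    xi: float
    sigma: float


def _xi(e: float) -> float:
    return e / (1.0 - e * e) - 0.5 * math.log((1.0 + e) / (1.0 - e))


def spheroid_rotational_drag(radius: float, eccentricity: float, viscosity: float) -> SpheroidDrag:
    """Rotational drag coefficient ``sigma = 16 e^3 / (3 xi(e)) * pi eta R^3``.

    ``R`` is the semi-major axis and ``e`` the eccentricity; ``e -> 0``
    recovers the sphere value ``8 pi eta R^3``.  Small eccentricities
    (``e < 1e-2``) are routed through the series expansion of the
    coefficient, ``8 / (1 + 6/5 e^2 + 9/7 e^4 + 4/3 e^6)``, to avoid the
    catastrophic cancellation in ``xi`` near zero.

    Parameters are SI: radius in metres, viscosity in Pa s (micron-scale
    callers may pass microns; only ``sigma``'s unit changes).
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if viscosity <= 0:
        raise ValueError("viscosity must be positive")
    e = float(eccentricity)
    if not 0.0 <= e < 1.0:
        raise ValueError(f"eccentricity must satisfy 0 <= e < 1, got {e}")
    if e < 1e-2:
        e2 = e * e
        coeff = 8.0 / (1.0 + 1.2 * e2 + (9.0 / 7.0) * e2**2 + (4.0 / 3.0) * e2**3)
        xi = 16.0 * e**3 / (3.0 * coeff) if e > 0 else 0.0
    else:
        xi = _xi(e)
        coeff = 16.0 * e**3 / (3.0 * xi)
    sigma = coeff * math.pi * viscosity * radius**3
    return SpheroidDrag(radius, e, viscosity, xi, sigma)


@dataclass(frozen=True)
class TorqueEstimate:
    """Ratio of flagellar torques implied by drag and angular-speed ratios."""

    sigma_ratio: float
    omega_ratio: float

    @property
    def torque_ratio(self) -> float:
        return self.sigma_ratio * self.omega_ratio


def round_to_1sf(x: float) -> float:
    """Round to one significant figure (used when quoting order estimates)."""
    if x == 0:
        return 0.0
    exp = math.floor(math.log10(abs(x)))
    return round(x, -exp)


def torque_ratio(sigma_ratio: float, omega_ratio: float) -> TorqueEstimate:
    """Torque ratio ``L1/L2 = (sigma1/sigma2) * (omega1/omega2)``.

    Viscous torque is ``L = sigma * omega``, so the ratio of torques of two
    rotating bodies is the product of their drag-coefficient and
    angular-speed ratios.
    """
    if sigma_ratio <= 0 or omega_ratio <= 0:
        raise ValueError("ratios must be positive")
    return TorqueEstimate(sigma_ratio, omega_ratio)


# ---------------------------------------------------------------------------
# Boundary-integral mobility of a sphere above a no-slip wall
# ---------------------------------------------------------------------------


def _assemble_wall_system(mesh: SphereMesh, viscosity: float) -> np.ndarray:
    """Dense first-kind system for the mobility problem.

    Unknowns: panel tractions ``q`` (3N) then rigid velocities ``(U, Omega)``
    (6).  Rows: no-slip collocation at panel centroids (3N), then total
    force and torque constraints (6).
    """
    x = mesh.centroids
    n = mesh.n_panels
    areas = mesh.areas
    eps = mesh.panel_radius()
    I = np.eye(3)

    # baseline midpoint rule: K_int[m, n] = integral of G over panel n
    K_int = areas[None, :, None, None] * (oseen_tensor(x, x) + _image_correction(x, x))

    images = x * np.array([1.0, 1.0, -1.0])
    dist = np.linalg.norm(x[:, None, :] - x[None, :, :], axis=-1)
    dist_im = np.linalg.norm(x[:, None, :] - images[None, :, :], axis=-1)

    def _disk_self(area: float, normal: np.ndarray) -> np.ndarray:
        # flat-disk integral of the Stokeslet about its center
        e = np.sqrt(area / np.pi)
        nn = np.outer(normal, normal)
        return 2.0 * np.pi * e * I + np.pi * e * (I - nn)

    # self panels: subdivided direct integral, disk rule on the central patch
    for m in range(n):
        s = 5
        pts, sub_a, sub_n = mesh.subdivide(m, s)
        d = np.linalg.norm(pts - x[m], axis=1)
        ctr = int(np.argmin(d))
        blk = _disk_self(sub_a[ctr], sub_n[ctr])
        keep = np.arange(len(sub_a)) != ctr
        blk = blk + np.einsum(
            "k,okij->ij", sub_a[keep], oseen_tensor(x[m][None], pts[keep])
        )
        K_int[m, m] = blk + areas[m] * _image_correction(x[m][None], x[m][None])[0, 0]

    # near-singular refinement for close direct and image interactions
    near_direct = (dist < 4.0 * eps[None, :]) & ~np.eye(n, dtype=bool)
    near_image = dist_im < 4.0 * eps[None, :]
    for m, nn_ in zip(*np.nonzero(near_direct)):
        s = int(np.clip(np.ceil(4.0 * eps[nn_] / max(dist[m, nn_], 1e-12)), 3, 15))
        pts, sub_a, _ = mesh.subdivide(nn_, s)
        direct = np.einsum("k,okij->ij", sub_a, oseen_tensor(x[m][None], pts))
        K_int[m, nn_] = direct + areas[nn_] * _image_correction(x[m][None], x[nn_][None])[0, 0]
    for m, nn_ in zip(*np.nonzero(near_image)):
        s = int(np.clip(np.ceil(8.0 * eps[nn_] / max(dist_im[m, nn_], 1e-12)), 3, 21))
        pts, sub_a, _ = mesh.subdivide(nn_, s)
        img = np.einsum("k,okij->ij", sub_a, _image_correction(x[m][None], pts))
        K_int[m, nn_] = K_int[m, nn_] - areas[nn_] * _image_correction(
            x[m][None], x[nn_][None]
        )[0, 0] + img

    K = K_int.transpose(0, 2, 1, 3).reshape(3 * n, 3 * n) / (8.0 * np.pi * viscosity)

    d = x - mesh.center
    P = np.zeros((3 * n, 6))
    C = np.zeros((6, 3 * n))
    for m in range(n):
        sk = np.array(
            [
                [0.0, -d[m, 2], d[m, 1]],
                [d[m, 2], 0.0, -d[m, 0]],
                [-d[m, 1], d[m, 0], 0.0],
            ]
        )
        P[3 * m : 3 * m + 3, :3] = I
        P[3 * m : 3 * m + 3, 3:] = -sk
        C[:3, 3 * m : 3 * m + 3] = areas[m] * I
        C[3:, 3 * m : 3 * m + 3] = areas[m] * sk

    A = np.zeros((3 * n + 6, 3 * n + 6))
    A[: 3 * n, : 3 * n] = K
    A[: 3 * n, 3 * n :] = -P
    A[3 * n :, : 3 * n] = C
    return A


def sphere_wall_grand_mobility(
    gap_over_R: float,
    n_theta: int = 16,
    n_phi: int = 20,
    grading: float = 2.5,
    radius: float = 1.0,
    viscosity: float = 1.0,
) -> np.ndarray:
    """6x6 grand mobility ``(U, Omega) = M (F, L)`` of a sphere near a wall.

    The sphere surface is discretized into constant-traction panels; the
    wall enters exactly through the image-system Green's function, so only
    the sphere is meshed.  The mesh is graded towards the near-wall pole.

    Raises
    ------
    ValueError for non-positive gap; numpy.linalg.LinAlgError if the dense
    solve fails.
    """
    if gap_over_R <= 0:
        raise ValueError("gap must be positive")
    h = radius * (1.0 + gap_over_R)
    mesh = sphere_mesh(radius, np.array([0.0, 0.0, h]), n_theta, n_phi, grading)
    A = _assemble_wall_system(mesh, viscosity)
    lu = lu_factor(A)
    n3 = 3 * mesh.n_panels
    M = np.zeros((6, 6))
    for k in range(6):
        rhs = np.zeros(n3 + 6)
        rhs[n3 + k] = 1.0
        sol = lu_solve(lu, rhs)
        M[:, k] = sol[n3:]
    return M


@dataclass(frozen=True)
class WallMobility:
    """Predicted slip of a torque-driven sphere as a function of wall gap.

    ``q_pred[i]`` is ``U_x / (Omega_y R)`` for a unit torque applied about
    ``y`` (parallel to the wall) at gap ``gaps[i] = d/R``; 1 would be
    perfect no-slip rolling, 0 full slip.
    """

    gaps: np.ndarray
    q_pred: np.ndarray
    n_panels: int
    mobilities: list = field(repr=False, default_factory=list)

    @property
    def q_max(self) -> float:
        return float(np.max(self.q_pred))


def wall_mobility_torque_driven_sphere(
    gaps_over_R: np.ndarray,
    n_theta: int = 32,
    n_phi: int = 40,
    grading: float = 3.0,
) -> WallMobility:
    """Slip ratio ``Q(d/R)`` of a force-free sphere driven by a wall-parallel torque.

    For each gap the mobility problem is solved with zero net force and a
    torque about ``y``; the wall breaks fore-aft symmetry and couples the
    rotation to a translation along ``x`` (the rolling direction).  In free
    space the coupling vanishes, so ``Q -> 0`` as ``d/R`` grows.
    """
    gaps = np.asarray(gaps_over_R, dtype=float)
    if np.any(gaps <= 0):
        raise ValueError("all gaps must be positive")
    if n_theta * n_phi < 320:
        raise ValueError("mesh too coarse: need at least 320 panels")
    q = np.empty_like(gaps)
    mobilities = []
    for i, g in enumerate(gaps):
        M = sphere_wall_grand_mobility(g, n_theta=n_theta, n_phi=n_phi, grading=grading)
        # U_x / Omega_y at radius 1; the direct coupling entry M[0,4]
        # converges markedly faster with panel count than its transpose,
        # so it is used unaveraged (the difference is a discretization
        # diagnostic, see the symmetry test)
        q[i] = M[0, 4] / M[4, 4]
        mobilities.append(M)
    return WallMobility(gaps=gaps, q_pred=q, n_panels=n_theta * n_phi, mobilities=mobilities)


# ---------------------------------------------------------------------------
# Resistive-force-theory flagellated sphere
# ---------------------------------------------------------------------------


@dataclass
class FlagellatedSphereParams:
    """Geometry and drive of a sphere propelled by a rotating helical filament.

    The filament is anchored on the sphere surface along ``anchor_dir``
    (unit vector from the center) and its helical axis points along
    ``axis`` (unit vector, typically outward).  ``motor_speed`` is the
    rotation rate of the filament about its axis relative to the body,
    in rad/s; the sign encodes the motor state (negative = CW as seen
    from outside looking back at the cell).  Lengths in sphere radii.
    """

    radius: float = 1.0
    anchor_dir: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    helix_radius: float = 0.1
    helix_pitch: float = 0.5
    helix_length: float = 3.0
    filament_radius: float = 0.005
    motor_speed: float = 100.0
    gap: float = 0.3
    n_segments: int = 60

    def __post_init__(self) -> None:
        self.anchor_dir = np.asarray(self.anchor_dir, float)
        self.axis = np.asarray(self.axis, float)
        for name in ("radius", "helix_radius", "helix_pitch", "helix_length", "filament_radius"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.helix_length <= self.helix_pitch:
            raise ValueError("helix length must exceed one pitch")
        for v in (self.anchor_dir, self.axis):
            if abs(np.linalg.norm(v) - 1.0) > 1e-9:
                raise ValueError("direction vectors must be unit")


def _gray_hancock_coefficients(params: FlagellatedSphereParams, viscosity: float):
    """Tangential/normal drag per unit length of a slender filament."""
    lam = params.helix_pitch
    a = params.filament_radius
    log_term = math.log(2.0 * lam / a)
    zeta_t = 2.0 * math.pi * viscosity / (log_term - 0.5)
    zeta_n = 4.0 * math.pi * viscosity / (log_term + 0.5)
    return zeta_t, zeta_n


def _helix_centerline(params: FlagellatedSphereParams, phase: float):
    """Filament centerline points and tangents in the body frame.

    The helix winds about ``axis`` starting from the surface anchor;
    ``phase`` advances the helix about its own axis (motor rotation).
    Right-handed helix.
    """
    axis = params.axis
    # orthonormal frame (e1, e2, axis)
    ref = np.array([0.0, 0.0, 1.0]) if abs(axis[2]) < 0.9 else np.array([1.0, 0.0, 0.0])
    e1 = np.cross(axis, ref)
    e1 /= np.linalg.norm(e1)
    e2 = np.cross(axis, e1)
    k = 2.0 * np.pi / params.helix_pitch
    s = np.linspace(0.0, params.helix_length, params.n_segments + 1)
    smid = 0.5 * (s[:-1] + s[1:])
    ds = np.diff(s)
    base = params.radius * params.anchor_dir
    ang = k * smid + phase
    pts = (
        base[None, :]
        + smid[:, None] * axis[None, :]
        + params.helix_radius * (np.cos(ang)[:, None] * e1 + np.sin(ang)[:, None] * e2)
    )
    tang = (
        axis[None, :]
        + params.helix_radius * k * (-np.sin(ang)[:, None] * e1 + np.cos(ang)[:, None] * e2)
    )
    tang /= np.linalg.norm(tang, axis=1, keepdims=True)
    return pts, tang, ds


def simulate_flagellated_sphere(
    params: FlagellatedSphereParams,
    telegraph: MotorTelegraph,
    total_time: float,
    dt: float,
    viscosity: float = 1.0,
    mobility_gaps: np.ndarray | None = None,
    mobility_tables: list | None = None,
    n_theta: int = 10,
    n_phi: int = 12,
):
    """Trajectory of a force- and torque-free flagellated sphere near a wall.

    Each step solves the balance: the filament, rotating at the motor
    speed relative to the body, exerts resistive-force-theory drag that
    depends linearly on the unknown rigid-body velocities ``(U, Omega)``;
    the sphere resists through its wall-corrected grand resistance
    (inverse of the boundary-integral mobility, interpolated in ``d/R``).
    The composite is force- and torque-free, closing the 6x6 system.

    Returns a dict with times, positions (sphere center), orientations
    (rotation matrices body->lab), angular velocities, and motor states.
    Integration halts with a ``"contact"`` flag if the sphere touches the
    wall.  The filament feels free-space drag only (no wall correction);
    only the sphere senses the wall.
    """
    from .trajectory import Trajectory  # local import to avoid cycle

    if total_time <= 0 or dt <= 0:
        raise ValueError("total_time and dt must be positive")
    if params.gap <= 0:
        raise ValueError("gap must be positive")
    if mobility_gaps is None:
        mobility_gaps = np.array([0.05, 0.1, 0.2, 0.3, 0.5, 1.0, 2.0, 5.0])
        mobility_tables = [
            sphere_wall_grand_mobility(g, n_theta=n_theta, n_phi=n_phi) for g in mobility_gaps
        ]
    mob = np.array(mobility_tables)  # (G, 6, 6)

    zeta_t, zeta_n = _gray_hancock_coefficients(params, viscosity)
    R = params.radius
    times = np.arange(0.0, total_time + 0.5 * dt, dt)
    n_steps = len(times)
    pos = np.zeros((n_steps, 3))
    pos[0] = np.array([0.0, 0.0, R + params.gap])
    Rbody = np.eye(3)
    orientations = np.zeros((n_steps, 3, 3))
    orientations[0] = Rbody
    omegas = np.zeros((n_steps, 3))
    states = np.empty(n_steps, dtype=object)
    phase = 0.0
    contact = False

    for it in range(n_steps - 1):
        t = times[it]
        state = telegraph.state_at(t)
        states[it] = state
        sgn = -1.0 if state == "CW" else 1.0
        motor = sgn * abs(params.motor_speed)

        gap = (pos[it, 2] - R) / R
        if gap <= 0:
            contact = True
            break
        gq = np.clip(gap, mobility_gaps[0], mobility_gaps[-1])
        M = np.empty((6, 6))
        for a in range(6):
            for b in range(6):
                M[a, b] = np.interp(gq, mobility_gaps, mob[:, a, b])
        resist = np.linalg.inv(M)

        pts_b, tang_b, ds = _helix_centerline(params, phase)
        pts = pos[it] + pts_b @ Rbody.T
        tang = tang_b @ Rbody.T
        axis_lab = Rbody @ params.axis
        rrel = pts - pos[it]
        # filament segment velocity = U + Omega x r + motor * (axis x r_ax)
        # where r_ax is position relative to the helix axis line
        base_lab = pos[it] + (params.radius * params.anchor_dir) @ Rbody.T
        r_ax = (pts - base_lab) - ((pts - base_lab) @ axis_lab)[:, None] * axis_lab
        v_motor = motor * np.cross(axis_lab, r_ax)

        # drag matrix per segment: zeta_n I + (zeta_t - zeta_n) t t^T
        TT = tang[:, :, None] * tang[:, None, :]
        D = zeta_n * np.eye(3)[None] + (zeta_t - zeta_n) * TT  # (S, 3, 3)
        Dds = D * ds[:, None, None]

        # F_flag(U, Omega) = -sum Dds (U + Omega x r + v_motor)
        # assemble linear map: columns for U (3) and Omega (3)
        S = len(ds)
        B = np.zeros((6, 6))
        A0 = np.zeros(6)
        sumD = Dds.sum(axis=0)
        B[:3, :3] = -sumD
        skew_r = np.zeros((S, 3, 3))
        skew_r[:, 0, 1] = -rrel[:, 2]
        skew_r[:, 0, 2] = rrel[:, 1]
        skew_r[:, 1, 0] = rrel[:, 2]
        skew_r[:, 1, 2] = -rrel[:, 0]
        skew_r[:, 2, 0] = -rrel[:, 1]
        skew_r[:, 2, 1] = rrel[:, 0]
        # Omega x r = -skew(r) Omega
        DskewR = np.einsum("sij,sjk->sik", Dds, -skew_r)
        B[:3, 3:] = -DskewR.sum(axis=0)
        f_const = -np.einsum("sij,sj->si", Dds, v_motor)  # (S, 3)
        A0[:3] = f_const.sum(axis=0)
        # torque about sphere center: sum r x f
        B[3:, :3] = -np.einsum("sij,sjk->ik", skew_r, Dds)
        B[3:, 3:] = -np.einsum("sij,sjk->ik", skew_r, DskewR)
        A0[3:] = np.cross(rrel, f_const).sum(axis=0)

        # force balance: -resist V + A0 + B V = 0
        V = np.linalg.solve(resist - B, A0)
        U, Omega = V[:3], V[3:]
        omegas[it] = Omega
        pos[it + 1] = pos[it] + U * dt
        dR = Rotation.from_rotvec(Omega * dt).as_matrix()
        Rbody = dR @ Rbody
        phase += motor * dt
        orientations[it + 1] = Rbody

    last = it + 1 if not contact else it
    states[last] = telegraph.state_at(times[min(last, n_steps - 1)])
    traj = Trajectory(
        times=times[: last + 1],
        positions=pos[: last + 1],
        unit_id="flagellated-sphere",
        kind="rosette",
        states=[s if s is not None else "CW" for s in states[: last + 1]],
    )
    return {
        "trajectory": traj,
        "orientations": orientations[: last + 1],
        "omega": omegas[: last + 1],
        "contact": contact,
    }


# ---------------------------------------------------------------------------
# Binomial flagellation model
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlagellationModel:
    """Independent-cell model for the number of active flagella on a rosette.

    Each of the ``n_cells`` members carries an active flagellum during a
    window ``active_window`` of its division cycle ``division_time``
    (minutes), so independently with probability ``f = active_window /
    division_time``.
    """

    n_cells: int = 25
    division_time: float = 100.0
    active_window: float = 1.0

    @property
    def f(self) -> float:
        return self.active_window / self.division_time

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if not 0.0 <= self.f <= 1.0:
            raise ValueError("active fraction f must lie in [0, 1]")


def flagellation_probability(model: FlagellationModel) -> float:
    """Probability that two or more member cells are simultaneously flagellated.

    Exact binomial tail ``P(X >= 2)`` with ``X ~ Binomial(N_s, f)``:
    ``1 - (1-f)^N - N f (1-f)^(N-1)``.
    """
    f = model.f
    n = model.n_cells
    return 1.0 - (1.0 - f) ** n - n * f * (1.0 - f) ** (n - 1)
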