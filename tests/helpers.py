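"""Shared independent oracles for the test suite.

These deliberately avoid the implementation paths they check: the
reflection expansion below touches only the raw image-system kernel and
builds the sphere-wall coupling from singularity solutions + Faxen laws,
never from the panel solver.
"""

from __future__ import annotations

import numpy as np

from rosetteroll.stokes import _image_correction

_EPS3 = np.zeros((3, 3, 3))
for _i, _j, _k in [(0, 1, 2), (1, 2, 0), (2, 0, 1)]:
    _EPS3[_i, _j, _k] = 1.0
    _EPS3[_i, _k, _j] = -1.0


def _dG_source(x: np.ndarray, x0: np.ndarray, step: float) -> np.ndarray:
    """d/dx0_k of the wall image tensor, dG[k, i, j]."""
    out = np.zeros((3, 3, 3))
    for k in range(3):
        e = np.zeros(3)
        e[k] = step
        out[k] = (
            _image_correction(x[None], (x0 + e)[None])[0, 0]
            - _image_correction(x[None], (x0 - e)[None])[0, 0]
        ) / (2 * step)
    return out


def _field_ops(f, x0: np.ndarray, d: float):
    u0 = f(x0)
    J = np.zeros((3, 3))
    lap = np.zeros(3)
    for k in range(3):
        e = np.zeros(3)
        e[k] = d
        up, um = f(x0 + e), f(x0 - e)
        J[:, k] = (up - um) / (2 * d)
        lap += (up + um - 2 * u0) / d**2
    return u0, J, lap


def reflection_slip_ratio(h_over_a: float, second: bool = True) -> float:
    """Q = U/(Omega a) of a torque-driven sphere near a wall, by reflections.

    First reflection: the sphere is a rotlet whose wall image advects it
    (Faxen translation law) and spins it (curl).  Second reflection: the
    image strain induces a stresslet S = (20/3) pi mu a^3 E on the
    force/torque-free sphere whose own wall image feeds back.  Leading
    term converges to the (1/8)(a/h)^4 far-field law.
    """
    a = 1.0
    x0 = np.array([0.0, 0.0, h_over_a * a])
    T = np.array([0.0, 1.0, 0.0])
    step = 1e-4 * h_over_a

    def u1(x):
        dG = _dG_source(x, x0, step)
        return 0.5 * np.einsum("lkj,l,kij->i", _EPS3, T, dG)

    d = 1e-3 * h_over_a
    u0, J, lap = _field_ops(u1, x0, d)
    curl = np.array([J[2, 1] - J[1, 2], J[0, 2] - J[2, 0], J[1, 0] - J[0, 1]])
    U = u0 + (a**2 / 6) * lap
    Om = T / a**3 + 0.5 * curl

    if second:
        E = 0.5 * (J + J.T)
        S = (20.0 / 3.0) * np.pi * a**3 * E

        def u2(x):
            dG = _dG_source(x, x0, step)
            sym = 0.5 * (dG + dG.transpose(2, 1, 0))
            return -(1.0 / (8 * np.pi)) * np.einsum("jk,kij->i", S, sym)

        v0, J2, lap2 = _field_ops(u2, x0, d)
        curl2 = np.array([J2[2, 1] - J2[1, 2], J2[0, 2] - J2[2, 0], J2[1, 0] - J2[0, 1]])
        U = U + v0 + (a**2 / 6) * lap2
        Om = Om + 0.5 * curl2
    return float(U[0] / (Om[1] * a))


def brute_force_msd(xy: np.ndarray, max_lag: int) -> np.ndarray:
    """Direct-loop time-averaged MSD, the oracle for the FFT version."""
    return np.array(
        [np.mean(np.sum((xy[k:] - xy[:-k]) ** 2, axis=1)) for k in range(1, max_lag + 1)]
    )


def match_events(detected: np.ndarray, true: np.ndarray, tol: float):
    """Greedy matching of detected to true event times; returns (tp, fp, fn)."""
    used = np.zeros(len(detected), dtype=bool)
    tp = fn = 0
    for t in true:
        if len(detected) == 0:
            fn += 1
            continue
        j = int(np.argmin(np.abs(detected - t)))
        if abs(detected[j] - t) < tol and not used[j]:
            tp += 1
            used[j] = True
        else:
            fn += 1
    fp = int((~used).sum())
    return tp, fp, fn
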