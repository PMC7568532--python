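"""Stokes-flow singularity kernels and sphere surface meshes.

Implements the free-space Oseen tensor and the half-space (image-system)
Green's function for a point force above a rigid no-slip plane wall at
``z = 0``.  These kernels are the building blocks of the boundary-integral
mobility solver in :mod:`rosetteroll.hydro`.

Conventions: the wall occupies ``z <= 0``; the fluid fills ``z > 0``; all
kernels omit the ``1 / (8 pi mu)`` prefactor, which callers apply once.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "oseen_tensor",
    "blake_tensor",
    "SphereMesh",
    "sphere_mesh",
]

_EZ = np.array([0.0, 0.0, 1.0])


def oseen_tensor(field: np.ndarray, source: np.ndarray) -> np.ndarray:
    """Pairwise free-space Stokeslet tensor.

    Parameters
    ----------
    field
        Field points, shape ``(N, 3)``.
    source
        Source points, shape ``(M, 3)``.

    Returns
    -------
    ndarray of shape ``(N, M, 3, 3)``: ``S_ij = d_ij/r + r_i r_j / r^3``.
    Pairs with zero separation yield ``inf``; callers owning a self term
    must replace those entries.
    """
    field = np.atleast_2d(np.asarray(field, dtype=float))
    source = np.atleast_2d(np.asarray(source, dtype=float))
    d = field[:, None, :] - source[None, :, :]
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.linalg.norm(d, axis=-1)
        inv_r = 1.0 / r
        inv_r3 = inv_r**3
        out = np.eye(3) * inv_r[..., None, None]
        out += d[..., :, None] * d[..., None, :] * inv_r3[..., None, None]
    return out


def _image_correction(field: np.ndarray, source: np.ndarray) -> np.ndarray:
    """Image-system part of the wall Green's function (Blake's solution).

    Returns the pairwise tensor ``G_wall - S`` where ``S`` is the direct
    Stokeslet; the result is regular for all field points in the fluid as
    long as no field point coincides with an image point.
    """
    field = np.atleast_2d(np.asarray(field, dtype=float))
    source = np.atleast_2d(np.asarray(source, dtype=float))
    if np.any(source[:, 2] <= 0):
        raise ValueError("source points must lie above the wall (z > 0)")
    h = source[:, 2]
    image = source * np.array([1.0, 1.0, -1.0])
    R = field[:, None, :] - image[None, :, :]
    Rn = np.linalg.norm(R, axis=-1)
    inv3 = Rn**-3
    inv5 = Rn**-5
    I = np.eye(3)
    RR = R[..., :, None] * R[..., None, :]
    # D_ik = d/dR_k [ h R_i/R^3 - delta_i3/R - R_i R_3/R^3 ]
    D = (
        h[None, :, None, None] * (I * inv3[..., None, None] - 3.0 * RR * inv5[..., None, None])
        + _EZ[:, None] * R[..., None, :] * inv3[..., None, None]
        - (I * R[..., 2, None, None] + R[..., :, None] * _EZ[None, :]) * inv3[..., None, None]
        + 3.0 * R[..., 2, None, None] * RR * inv5[..., None, None]
    )
    # mirror the source index: multiply column j=z by -1
    D[..., :, 2] *= -1.0
    G = -oseen_tensor(field, image) + 2.0 * h[None, :, None, None] * D
    return G


def blake_tensor(field: np.ndarray, source: np.ndarray) -> np.ndarray:
    """Pairwise Green's function for a Stokeslet above a no-slip wall.

    ``G = S(direct) + image correction``; velocities vanish identically on
    the plane ``z = 0``.
    """
    return oseen_tensor(field, source) + _image_correction(field, source)


@dataclass(frozen=True)
class SphereMesh:
    """Constant-density panel mesh of a sphere surface.

    Attributes
    ----------
    centroids : (N, 3) collocation points on the sphere surface
    normals : (N, 3) outward unit normals
    areas : (N,) exact spherical patch areas
    theta_bounds, phi_bounds : (N, 2) patch extents, for sub-quadrature
    radius : sphere radius
    center : (3,) sphere center
    """

    centroids: np.ndarray
    normals: np.ndarray
    areas: np.ndarray
    theta_bounds: np.ndarray
    phi_bounds: np.ndarray
    radius: float
    center: np.ndarray

    @property
    def n_panels(self) -> int:
        return len(self.areas)

    def panel_radius(self) -> np.ndarray:
        """Equal-area flat-disk radius of each panel."""
        return np.sqrt(self.areas / np.pi)

    def subdivide(self, n: int, s: int):
        """Split panel ``n`` into ``s x s`` sub-patches uniform in (cos t, phi).

        Returns sub-collocation points on the sphere, sub-areas and outward
        normals.  For odd ``s`` the central sub-patch midpoint coincides
        with the parent collocation point.
        """
        c1, c2 = np.cos(self.theta_bounds[n])
        p1, p2 = self.phi_bounds[n]
        ce = np.linspace(c1, c2, s + 1)
        pe = np.linspace(p1, p2, s + 1)
        cm = 0.5 * (ce[:-1] + ce[1:])
        pm = 0.5 * (pe[:-1] + pe[1:])
        CM, PM = np.meshgrid(cm, pm, indexing="ij")
        areas = (self.radius**2) * np.abs(np.diff(ce))[:, None] * np.diff(pe)[None, :]
        st = np.sqrt(np.maximum(1.0 - CM**2, 0.0))
        normals = np.stack([st * np.cos(PM), st * np.sin(PM), CM], axis=-1).reshape(-1, 3)
        pts = self.center + self.radius * normals
        return pts, areas.reshape(-1), normals


def sphere_mesh(
    radius: float,
    center: np.ndarray,
    n_theta: int = 16,
    n_phi: int = 20,
    grading: float = 2.0,
) -> SphereMesh:
    """Latitude-longitude panel mesh with grading towards the south pole.

    The south pole (minimum ``z``) faces the wall, so panels are clustered
    there to resolve the thinning lubrication gap.  ``grading > 1``
    concentrates latitude bands near the south pole; ``grading = 1`` is
    uniform in polar angle.

    Patch areas are exact (``R^2 (cos t1 - cos t2) dphi``) and collocation
    points sit on the sphere at the area centroid of each patch.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    if n_theta < 2 or n_phi < 3:
        raise ValueError("mesh too coarse: need n_theta >= 2, n_phi >= 3")
    center = np.asarray(center, dtype=float)
    u = np.linspace(0.0, 1.0, n_theta + 1)
    theta_edges = np.pi * u ** (1.0 / grading)  # clustered near theta = pi
    phi_edges = np.linspace(0.0, 2.0 * np.pi, n_phi + 1)

    t1 = theta_edges[:-1][:, None]
    t2 = theta_edges[1:][:, None]
    dphi = np.diff(phi_edges)[None, :]
    areas = (radius**2) * (np.cos(t1) - np.cos(t2)) * dphi
    # collocation at the area centroid: mid-cos latitude, mid phi
    cos_tc = 0.5 * (np.cos(t1) + np.cos(t2))
    theta_c = np.broadcast_to(np.arccos(cos_tc), areas.shape)
    phi_c = np.broadcast_to(0.5 * (phi_edges[:-1] + phi_edges[1:])[None, :], areas.shape)

    st = np.sin(theta_c)
    normals = np.stack(
        [st * np.cos(phi_c), st * np.sin(phi_c), np.cos(theta_c)], axis=-1
    ).reshape(-1, 3)
    centroids = center + radius * normals
    nb = areas.shape
    tb = np.broadcast_to(np.concatenate([t1, t2], axis=1)[:, None, :], (*nb, 2)).reshape(-1, 2)
    pb = np.broadcast_to(
        np.column_stack([phi_edges[:-1], phi_edges[1:]])[None, :, :], (*nb, 2)
    ).reshape(-1, 2)
    return SphereMesh(
        centroids=centroids,
        normals=normals,
        areas=areas.reshape(-1),
        theta_bounds=tb,
        phi_bounds=pb,
        radius=float(radius),
        center=center,
    )
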