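"""Constant-collocation boundary-element solver for nested conductor surfaces.

Solves the quasi-static surface-potential integral equation (double-layer
formulation) on closed triangulated surfaces: potentials are constant per
triangle, collocated at triangle centroids, with analytic solid-angle
element integrals (van Oosterom & Strackee).  The rank-1 nullspace of the
operator (the arbitrary constant potential) is removed by deflation and the
system is LU-factorized once, so repeated dipole solves are cheap.

Plain collocation is accurate for homogeneous and mild conductivity
contrasts; at the realistic ~1/79 skull contrast the formulation loses
accuracy (the classical isolated-skull correction is deliberately not
implemented here), so the multilayer-sphere series remains the production
engine and the BEM serves as an independent geometric solver and
cross-check.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import lu_factor, lu_solve

from .geometry import TriMesh, containing_triangle_barycentric
from .forward import Dipole

__all__ = ["BemOperator", "bem_assemble", "bem_potential", "solid_angles"]


def solid_angles(obs: np.ndarray, vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    """Signed solid angles of each triangle seen from each observation point.

    Returns an ``(n_obs, n_faces)`` array.  With outward-wound faces the
    angles of a closed surface sum to ``4 pi`` for an interior observation
    point and ``0`` outside (van Oosterom & Strackee 1983 formula).
    """
    obs = np.atleast_2d(np.asarray(obs, dtype=float))
    tri = vertices[faces]  # (n_f, 3, 3)
    out = np.empty((len(obs), len(faces)))
    block = max(1, int(2e6 // max(len(faces), 1)))
    for s in range(0, len(obs), block):
        o = obs[s:s + block]
        r = tri[None, :, :, :] - o[:, None, None, :]  # (b, f, 3, 3)
        n1 = np.linalg.norm(r[..., 0, :], axis=-1)
        n2 = np.linalg.norm(r[..., 1, :], axis=-1)
        n3 = np.linalg.norm(r[..., 2, :], axis=-1)
        r1, r2, r3 = r[..., 0, :], r[..., 1, :], r[..., 2, :]
        num = np.einsum("bfi,bfi->bf", r1, np.cross(r2, r3))
        den = (
            n1 * n2 * n3
            + np.einsum("bfi,bfi->bf", r1, r2) * n3
            + np.einsum("bfi,bfi->bf", r2, r3) * n1
            + np.einsum("bfi,bfi->bf", r3, r1) * n2
        )
        out[s:s + block] = 2.0 * np.arctan2(num, den)
    return out


@dataclass(frozen=True)
class BemOperator:
    """Factorized double-layer system for a set of nested closed surfaces."""

    surfaces: tuple[TriMesh, ...]
    sigma_in: tuple[float, ...]
    sigma_out: tuple[float, ...]
    centroids: np.ndarray
    surface_index: np.ndarray  # surface id per collocation point / triangle
    lu: tuple
    center: np.ndarray

    @property
    def n_triangles(self) -> int:
        return len(self.centroids)

    @property
    def outer_surface(self) -> TriMesh:
        return self.surfaces[-1]


def _check_nested(surfaces: tuple[TriMesh, ...], center: np.ndarray) -> None:
    rmax_prev = 0.0
    for k, s in enumerate(surfaces):
        r = np.linalg.norm(s.vertices - center, axis=1)
        if r.min() <= rmax_prev:
            raise ValueError(
                f"surfaces {k - 1} and {k} are not strictly nested "
                f"(min radius {r.min():.4f} <= previous max {rmax_prev:.4f})"
            )
        rmax_prev = r.max()


def bem_assemble(
    surfaces: list[TriMesh] | tuple[TriMesh, ...],
    conductivities: list[float] | tuple[float, ...],
) -> BemOperator:
    """Assemble and factorize the collocation system.

    ``conductivities`` lists one value per enclosed region, innermost
    first; the medium outside the last surface is non-conductive.  Surfaces
    must be closed, outward-wound and strictly nested (checked radially
    about the joint centroid, which is exact for the concentric geometry
    used here).
    """
    surfaces = tuple(surfaces)
    if len(conductivities) != len(surfaces):
        raise ValueError("need one conductivity per surface (enclosed region)")
    sigma_in = tuple(float(s) for s in conductivities)
    sigma_out = tuple(list(sigma_in[1:]) + [0.0])
    center = np.mean(
        np.concatenate([s.vertices for s in surfaces]), axis=0
    )
    _check_nested(surfaces, center)

    centroids = np.concatenate([s.vertices[s.faces].mean(axis=1) for s in surfaces])
    surf_idx = np.concatenate(
        [np.full(s.n_faces, k) for k, s in enumerate(surfaces)]
    )
    T = len(centroids)
    M = np.zeros((T, T))
    col0 = 0
    for j, s in enumerate(surfaces):
        w = (sigma_in[j] - sigma_out[j]) / (4.0 * np.pi)
        om = solid_angles(centroids, s.vertices, s.faces)
        M[:, col0:col0 + s.n_faces] = -w * om
        col0 += s.n_faces
    # principal value: a flat triangle subtends no solid angle at its own
    # centroid, but the arctan formula is ill-defined there
    np.fill_diagonal(M, 0.0)
    diag = 0.5 * (np.asarray(sigma_in) + np.asarray(sigma_out))[surf_idx]
    M[np.arange(T), np.arange(T)] += diag
    # deflate the constant-potential nullspace
    M += (diag.mean() / T)
    lu = lu_factor(M, overwrite_a=True, check_finite=False)
    return BemOperator(
        surfaces, sigma_in, sigma_out, centroids, surf_idx, lu, center
    )


def _solve_boundary(op: BemOperator, dipole: Dipole) -> np.ndarray:
    """Boundary potentials on all collocation points for one dipole."""
    d = op.centroids - dipole.position
    r3 = np.linalg.norm(d, axis=1) ** 3
    g = (d @ dipole.moment) / (4.0 * np.pi * r3)  # sigma_src * V_infinite
    v = lu_solve(op.lu, g, check_finite=False)
    return v - v.mean()


def bem_potential(
    op: BemOperator, dipole: Dipole, electrode_positions: np.ndarray
) -> np.ndarray:
    """Potentials at electrodes on (or near) the outermost surface.

    The boundary solution is interpolated barycentrically within the
    containing triangle, using vertex values averaged from the incident
    triangles.
    """
    b = np.linalg.norm(dipole.position - op.center)
    inner_min = np.linalg.norm(op.surfaces[0].vertices - op.center, axis=1).min()
    if b >= inner_min:
        raise ValueError(
            f"dipole at radius {b:.4f} m is not inside the innermost surface"
        )
    pts = np.atleast_2d(np.asarray(electrode_positions, dtype=float))
    outer = op.outer_surface
    r_out = np.linalg.norm(outer.vertices - op.center, axis=1).mean()
    off = np.abs(np.linalg.norm(pts - op.center, axis=1) - r_out)
    if off.max() > 5e-3:
        i = int(np.argmax(off))
        raise ValueError(
            f"electrode {i} is {off.max() * 1e3:.1f} mm from the outer surface"
        )
    v = _solve_boundary(op, dipole)
    v_outer = v[op.surface_index == len(op.surfaces) - 1]
    # vertex values: mean of incident triangle values
    vert_sum = np.zeros(outer.n_vertices)
    vert_cnt = np.zeros(outer.n_vertices)
    for k in range(3):
        np.add.at(vert_sum, outer.faces[:, k], v_outer)
        np.add.at(vert_cnt, outer.faces[:, k], 1.0)
    vert_val = vert_sum / vert_cnt
    fidx, w = containing_triangle_barycentric(outer, pts, op.center)
    return np.einsum("pk,pk->p", vert_val[outer.faces[fidx]], w)
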