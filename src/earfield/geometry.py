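"""Triangulated surface meshes and basic differential-geometry helpers.

All meshes used in this package are closed, consistently wound 2-manifolds
(boundary-element surfaces and the cortical source surface).  Construction
goes through :func:`make_sphere_mesh` or the validated :class:`TriMesh`
constructor; file round-trips live in :mod:`earfield.io`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import trimesh as _trimesh

__all__ = [
    "TriMesh",
    "MeshError",
    "make_sphere_mesh",
    "vertex_normals",
    "vertex_areas",
    "vertex_adjacency",
    "face_areas",
    "containing_triangle_barycentric",
]


class MeshError(ValueError):
    """Raised when a surface fails closed-manifold / orientation validation."""


@dataclass(frozen=True)
class TriMesh:
    """A closed triangulated 2-manifold surface.

    Parameters
    ----------
    vertices : (n_v, 3) float array, meters.
    faces : (n_f, 3) int array of vertex indices, consistent outward winding.
    """

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self):
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=float))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)
        validate_closed_manifold(v, f)

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    def area(self) -> float:
        return float(face_areas(self.vertices, self.faces).sum())


def validate_closed_manifold(vertices: np.ndarray, faces: np.ndarray) -> None:
    """Check index range, closedness (each edge in exactly 2 faces),
    consistent winding (each undirected edge appears once per direction)
    and absence of degenerate triangles."""
    if vertices.ndim != 2 or vertices.shape[1] != 3:
        raise MeshError("vertices must be an (n, 3) array")
    if faces.ndim != 2 or faces.shape[1] != 3:
        raise MeshError("faces must be an (m, 3) array")
    if faces.size == 0:
        raise MeshError("mesh has no faces")
    if faces.min() < 0 or faces.max() >= len(vertices):
        raise MeshError(
            f"face index out of range: max {faces.max()}, n_vertices {len(vertices)}"
        )
    a = face_areas(vertices, faces)
    if np.any(a <= 0) or np.any(~np.isfinite(a)):
        bad = int(np.argmin(a))
        raise MeshError(f"degenerate (zero-area) triangle at face {bad}")
    # directed edges: each (i->j) must occur exactly once, and its reverse once
    e = np.concatenate([faces[:, [0, 1]], faces[:, [1, 2]], faces[:, [2, 0]]])
    keys = e[:, 0].astype(np.int64) * len(vertices) + e[:, 1]
    uniq, counts = np.unique(keys, return_counts=True)
    if np.any(counts != 1):
        k = int(uniq[np.argmax(counts != 1)])
        raise MeshError(
            f"inconsistent winding or non-manifold edge "
            f"({k // len(vertices)}, {k % len(vertices)})"
        )
    rev = e[:, 1].astype(np.int64) * len(vertices) + e[:, 0]
    if not np.array_equal(np.sort(keys), np.sort(rev)):
        # some directed edge lacks its opposite: open surface
        missing = np.setdiff1d(keys, rev)
        k = int(missing[0])
        raise MeshError(
            f"open surface: edge ({k // len(vertices)}, {k % len(vertices)}) "
            "has no partner face"
        )


def face_areas(vertices: np.ndarray, faces: np.ndarray) -> np.ndarray:
    p = vertices[faces]
    n = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])
    return 0.5 * np.linalg.norm(n, axis=1)


def make_sphere_mesh(radius: float, subdivision_level: int,
                     center: np.ndarray | None = None) -> TriMesh:
    """Icosphere by recursive subdivision: ``20 * 4**level`` faces, all
    vertices on the sphere to machine precision, outward winding."""
    if subdivision_level < 0:
        raise ValueError(f"subdivision_level must be >= 0, got {subdivision_level}")
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    ico = _trimesh.creation.icosphere(subdivisions=subdivision_level, radius=1.0)
    v = np.asarray(ico.vertices, dtype=float)
    # re-normalise: unit sphere vertices, then exact scaling
    v = v / np.linalg.norm(v, axis=1, keepdims=True) * radius
    if center is not None:
        v = v + np.asarray(center, dtype=float)
    return TriMesh(v, np.asarray(ico.faces, dtype=np.int64))


def vertex_normals(mesh: TriMesh) -> np.ndarray:
    """Per-vertex unit normals from area-weighted face normals (the face
    cross product already carries the area weight)."""
    p = mesh.vertices[mesh.faces]
    fn = np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0])  # 2 * area * n̂
    out = np.zeros_like(mesh.vertices)
    for k in range(3):
        np.add.at(out, mesh.faces[:, k], fn)
    norms = np.linalg.norm(out, axis=1, keepdims=True)
    if np.any(norms == 0):
        raise MeshError("vertex with vanishing normal (degenerate star)")
    return out / norms


def vertex_areas(mesh: TriMesh) -> np.ndarray:
    """Barycentric vertex areas: one third of each incident face area.
    Sums exactly to the total surface area."""
    fa = face_areas(mesh.vertices, mesh.faces) / 3.0
    out = np.zeros(mesh.n_vertices)
    for k in range(3):
        np.add.at(out, mesh.faces[:, k], fa)
    return out


def vertex_adjacency(mesh: TriMesh) -> list[np.ndarray]:
    """Neighbour lists over mesh edges, sorted, one array per vertex."""
    e = np.concatenate(
        [mesh.faces[:, [0, 1]], mesh.faces[:, [1, 2]], mesh.faces[:, [2, 0]]]
    )
    both = np.concatenate([e, e[:, ::-1]])
    both = np.unique(both, axis=0)
    out: list[np.ndarray] = []
    split = np.searchsorted(both[:, 0], np.arange(mesh.n_vertices + 1))
    for i in range(mesh.n_vertices):
        out.append(both[split[i]:split[i + 1], 1].copy())
    return out


def containing_triangle_barycentric(
    mesh: TriMesh, points: np.ndarray, center: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray]:
    """For each point, find the mesh triangle containing its radial
    projection (rays from ``center``) and the barycentric weights there.

    Works for star-shaped surfaces around ``center`` (all surfaces in this
    package).  Returns ``(face_indices, weights)`` with weights summing to 1.
    """
    pts = np.atleast_2d(np.asarray(points, dtype=float))
    c = np.zeros(3) if center is None else np.asarray(center, dtype=float)
    d = pts - c
    d = d / np.linalg.norm(d, axis=1, keepdims=True)
    tri = mesh.vertices[mesh.faces] - c  # (n_f, 3, 3)
    face_idx = np.empty(len(pts), dtype=np.int64)
    weights = np.empty((len(pts), 3))
    # barycentric coordinates of the ray direction in the cone of each face:
    # solve d = w0*v0 + w1*v1 + w2*v2 (up to positive scale); containment
    # iff all w >= 0.  Done per point against all faces (meshes are small).
    for i, di in enumerate(d):
        w = np.linalg.solve(
            tri.transpose(0, 2, 1),
            np.broadcast_to(di[:, None], (len(tri), 3, 1)).copy(),
        )[..., 0]
        s = w.sum(axis=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            wn = w / s[:, None]
        ok = (s > 0) & np.all(wn > -1e-9, axis=1)
        if not np.any(ok):  # pragma: no cover - star-shaped meshes always hit
            raise MeshError(f"no containing triangle for point {pts[i]}")
        # pick the face with the least-negative minimum weight among hits
        cand = np.flatnonzero(ok)
        best = cand[np.argmax(wn[cand].min(axis=1))]
        face_idx[i] = best
        wb = np.clip(wn[best], 0.0, None)
        weights[i] = wb / wb.sum()
    return face_idx, weights
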