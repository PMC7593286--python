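"""Synthetic head geometry: conductor shells, folded cortex, montages, grids.

This module generates every geometric input the sensitivity analysis needs,
replacing subject anatomy with parameterized synthetic stand-ins that keep
the structure the analysis relies on: concentric conductor shells
(brain+CSF, skull, skin), a folded cortical surface whose outward normals
vary like gyri and sulci, a quasi-uniform ~128-channel cap, and C-shaped
10-electrode around-ear arrays.

Coordinate convention: origin at the shell center, +x anterior, +y left,
+z superior; all lengths in meters.
"""

from __future__ import annotations

import heapq
from collections import deque
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.special import sph_harm_y

from .geometry import (
    TriMesh,
    make_sphere_mesh,
    vertex_adjacency,
    vertex_areas,
    vertex_normals,
)

__all__ = [
    "ShellModel",
    "CorticalSurface",
    "ElectrodeMontage",
    "VolumeGrid",
    "Parcellation",
    "SyntheticHead",
    "make_shell_model",
    "make_synthetic_cortex",
    "make_cap_montage",
    "make_ceegrid_montage",
    "project_to_scalp",
    "make_volume_grid",
    "parcellate",
    "left_lateral_exclusion",
    "make_default_head",
    "DEFAULTS",
]

#: Default model parameters.  Shell radii/conductivities follow the standard
#: three-compartment reading (brain+CSF merged at 0.33 S/m since both carry
#: the same value, skull 0.0042 S/m, skin 0.33 S/m); the remaining scales
#: are chosen so that around-ear electrode-to-source distances land in the
#: few-centimeter range typical of around-ear recordings.
DEFAULTS = {
    "shell_radii": (0.08, 0.085, 0.092),
    "shell_conductivities": (0.33, 0.0042, 0.33),
    "cortex_base_radius": 0.065,
    "cortex_fold_amplitude": 0.15,
    "cortex_fold_degree_band": (8, 16),
    "cortex_subdivision_level": 4,
    "grid_spacing": 0.005,
    "grid_margin": 0.005,
    "cap_n_electrodes": 128,
    "cap_min_elevation_deg": -30.0,
    "ceegrid_ear_azimuth_deg": 90.0,
    "ceegrid_semi_axis_vertical": 0.035,
    "ceegrid_semi_axis_horizontal": 0.025,
    "ceegrid_gap_deg": 90.0,
    "montage_jitter_std": 0.001,
    "n_patches": 50,
    "medial_exclusion_y": 0.01,
    "source_amplitude": 1e-9,  # A*m, i.e. 1 nA*m per dipole
}


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class ShellModel:
    """Concentric spherical volume conductor.

    radii : outer radius per shell, meters, innermost first, increasing.
    conductivities : S/m per shell, innermost first.
    center : shell center, meters.
    """

    radii: tuple[float, ...]
    conductivities: tuple[float, ...]
    center: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self):
        radii = tuple(float(r) for r in self.radii)
        sig = tuple(float(s) for s in self.conductivities)
        object.__setattr__(self, "radii", radii)
        object.__setattr__(self, "conductivities", sig)
        object.__setattr__(
            self, "center", np.asarray(self.center, dtype=float).reshape(3)
        )
        if len(radii) != len(sig):
            raise ValueError(
                f"{len(radii)} radii but {len(sig)} conductivities"
            )
        if not 1 <= len(radii) <= 4:
            raise ValueError(f"1-4 shells supported, got {len(radii)}")
        if any(r <= 0 for r in radii) or any(
            b <= a for a, b in zip(radii, radii[1:])
        ):
            raise ValueError(f"radii must be positive and strictly increasing: {radii}")
        if any(s <= 0 for s in sig):
            raise ValueError(f"conductivities must be positive: {sig}")

    @property
    def inner_radius(self) -> float:
        return self.radii[0]

    @property
    def scalp_radius(self) -> float:
        return self.radii[-1]

    @property
    def n_shells(self) -> int:
        return len(self.radii)


def make_shell_model(
    radii: Sequence[float] = DEFAULTS["shell_radii"],
    conductivities: Sequence[float] = DEFAULTS["shell_conductivities"],
    center: Sequence[float] = (0.0, 0.0, 0.0),
) -> ShellModel:
    """Validated concentric-shell conductor model (see :class:`ShellModel`)."""
    return ShellModel(tuple(radii), tuple(conductivities), np.asarray(center))


@dataclass(frozen=True)
class CorticalSurface:
    """Closed folded source surface with per-vertex outward normals (the
    constrained dipole orientations) and barycentric vertex areas."""

    mesh: TriMesh
    normals: np.ndarray
    vertex_areas: np.ndarray

    def __post_init__(self):
        n = np.asarray(self.normals, dtype=float)
        a = np.asarray(self.vertex_areas, dtype=float)
        object.__setattr__(self, "normals", n)
        object.__setattr__(self, "vertex_areas", a)
        if n.shape != self.mesh.vertices.shape:
            raise ValueError("normals shape mismatch")
        if not np.allclose(np.linalg.norm(n, axis=1), 1.0, atol=1e-9):
            raise ValueError("normals must be unit vectors")
        if abs(a.sum() - self.mesh.area()) > 1e-9 * self.mesh.area():
            raise ValueError("vertex areas do not sum to the mesh area")

    @property
    def n_vertices(self) -> int:
        return self.mesh.n_vertices

    @classmethod
    def from_mesh(cls, mesh: TriMesh) -> "CorticalSurface":
        return cls(mesh, vertex_normals(mesh), vertex_areas(mesh))


@dataclass(frozen=True)
class ElectrodeMontage:
    """Labeled sensor positions on the scalp."""

    labels: tuple[str, ...]
    positions: np.ndarray
    side_tag: tuple[str, ...] | None = None

    def __post_init__(self):
        labels = tuple(str(x) for x in self.labels)
        pos = np.asarray(self.positions, dtype=float).reshape(-1, 3)
        object.__setattr__(self, "labels", labels)
        object.__setattr__(self, "positions", pos)
        if self.side_tag is not None:
            object.__setattr__(self, "side_tag", tuple(self.side_tag))
        if len(labels) != len(pos):
            raise ValueError("labels/positions length mismatch")
        if len(labels) < 2:
            raise ValueError("a montage needs at least 2 electrodes")
        if len(set(labels)) != len(labels):
            dup = sorted({x for x in labels if labels.count(x) > 1})
            raise ValueError(f"duplicate electrode labels: {dup}")

    @property
    def n_electrodes(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def validate_on_scalp(self, shell: ShellModel, tol: float = 1e-6) -> None:
        r = np.linalg.norm(self.positions - shell.center, axis=1)
        off = np.abs(r - shell.scalp_radius)
        if off.max() > tol:
            i = int(np.argmax(off))
            raise ValueError(
                f"electrode {self.labels[i]} is {off.max():.2e} m off the scalp"
            )

    def combined(self, other: "ElectrodeMontage") -> "ElectrodeMontage":
        """Concatenate two montages (e.g. left + right ear grids)."""
        tags = None
        if self.side_tag is not None and other.side_tag is not None:
            tags = self.side_tag + other.side_tag
        return ElectrodeMontage(
            self.labels + other.labels,
            np.vstack([self.positions, other.positions]),
            tags,
        )


@dataclass(frozen=True)
class VolumeGrid:
    """Isotropic cubic source lattice strictly inside the innermost shell."""

    points: np.ndarray
    spacing: float

    def __post_init__(self):
        object.__setattr__(
            self, "points", np.asarray(self.points, dtype=float).reshape(-1, 3)
        )
        if len(self.points) == 0:
            raise ValueError("volume grid has no points")

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class Parcellation:
    """Partition of the non-excluded cortex vertices into connected patches.

    patch_id : per-vertex patch index, -1 for excluded vertices.
    patch_areas : per-patch area in cm^2.
    """

    patch_id: np.ndarray
    n_patches: int
    patch_areas: np.ndarray

    def __post_init__(self):
        pid = np.asarray(self.patch_id, dtype=np.int64)
        object.__setattr__(self, "patch_id", pid)
        object.__setattr__(
            self, "patch_areas", np.asarray(self.patch_areas, dtype=float)
        )
        ids = np.unique(pid[pid >= 0])
        if len(ids) != self.n_patches or len(self.patch_areas) != self.n_patches:
            raise ValueError("patch bookkeeping inconsistent")

    def vertices_of(self, patch: int) -> np.ndarray:
        if not 0 <= patch < self.n_patches:
            raise KeyError(f"unknown patch id {patch}")
        return np.flatnonzero(self.patch_id == patch)


# ---------------------------------------------------------------------------
# generators


def make_synthetic_cortex(
    base_radius: float = DEFAULTS["cortex_base_radius"],
    fold_amplitude: float = DEFAULTS["cortex_fold_amplitude"],
    fold_degree_band: tuple[int, int] = DEFAULTS["cortex_fold_degree_band"],
    subdivision_level: int = DEFAULTS["cortex_subdivision_level"],
    seed: int = 0,
    shell: ShellModel | None = None,
) -> CorticalSurface:
    """Folded source surface: an icosphere with a band-limited random
    spherical-harmonic radial perturbation.

    The perturbation ``r(theta, phi) = base_radius * (1 + A * f)`` with
    ``f`` a zero-mean random combination of real spherical harmonics of
    degree ``l`` in ``fold_degree_band``, rescaled so ``max |f| = 1``.  At
    spectral degrees ~8-16 this produces gyrus/sulcus-like undulations whose
    outward normals deviate substantially from the radial direction, which
    is the property of real cortical folding that drives orientation
    sensitivity.  Deterministic for a fixed seed.
    """
    if not 0.0 <= fold_amplitude <= 0.3:
        raise ValueError(f"fold_amplitude must be in [0, 0.3], got {fold_amplitude}")
    lmin, lmax = fold_degree_band
    if lmin < 1 or lmax < lmin:
        raise ValueError(f"bad fold_degree_band {fold_degree_band}")
    base = make_sphere_mesh(1.0, subdivision_level)
    u = base.vertices  # unit directions
    theta = np.arccos(np.clip(u[:, 2], -1.0, 1.0))
    phi = np.arctan2(u[:, 1], u[:, 0])
    if fold_amplitude > 0:
        rng = np.random.default_rng(seed)
        f = np.zeros(len(u))
        for l in range(lmin, lmax + 1):
            for m in range(0, l + 1):
                y = sph_harm_y(l, m, theta, phi)
                a = rng.standard_normal()
                if m == 0:
                    f += a * y.real
                else:
                    b = rng.standard_normal()
                    f += np.sqrt(2.0) * (a * y.real + b * y.imag)
        f /= np.abs(f).max()
        radius = base_radius * (1.0 + fold_amplitude * f)
    else:
        radius = np.full(len(u), base_radius)
    verts = u * radius[:, None]
    if shell is not None:
        rmax = float(np.linalg.norm(verts, axis=1).max())
        if rmax >= shell.inner_radius:
            raise ValueError(
                f"cortex max radius {rmax:.4f} m reaches the innermost shell "
                f"({shell.inner_radius:.4f} m)"
            )
        verts = verts + shell.center
    mesh = TriMesh(verts, base.faces)
    return CorticalSurface.from_mesh(mesh)


def project_to_scalp(points: np.ndarray, shell: ShellModel) -> np.ndarray:
    """Scale points radially (from the shell center) onto the scalp sphere."""
    p = np.atleast_2d(np.asarray(points, dtype=float)) - shell.center
    r = np.linalg.norm(p, axis=1)
    if np.any(r == 0):
        raise ValueError("cannot project the shell center onto the scalp")
    out = p / r[:, None] * shell.scalp_radius + shell.center
    return out if np.asarray(points).ndim > 1 else out[0]


_GOLDEN_ANGLE = np.pi * (3.0 - np.sqrt(5.0))


def make_cap_montage(
    shell: ShellModel,
    n_electrodes: int = DEFAULTS["cap_n_electrodes"],
    min_elevation_deg: float = DEFAULTS["cap_min_elevation_deg"],
) -> ElectrodeMontage:
    """Quasi-uniform cap coverage via a Fibonacci lattice on the spherical
    cap with elevation >= ``min_elevation_deg`` (default -30 deg, i.e. the
    cap extends below the equator the way a dense EEG cap does)."""
    if n_electrodes < 2:
        raise ValueError("need at least 2 electrodes")
    z_min = np.sin(np.deg2rad(min_elevation_deg))
    if z_min >= 1.0:
        raise ValueError("empty cap region")
    i = np.arange(n_electrodes)
    z = z_min + (1.0 - z_min) * (i + 0.5) / n_electrodes
    az = i * _GOLDEN_ANGLE
    rho = np.sqrt(1.0 - z**2)
    pts = np.column_stack([rho * np.cos(az), rho * np.sin(az), z])
    pts = pts * shell.scalp_radius + shell.center
    labels = tuple(f"C{k + 1:03d}" for k in range(n_electrodes))
    return ElectrodeMontage(labels, pts, ("cap",) * n_electrodes)


#: Electrode label order around the C, from the anterior-superior tip over
#: the top of the ear, down the back, to the anterior-inferior tip.
CEEGRID_LABELS = ("1", "2", "3", "4", "4a", "4b", "5", "6", "7", "8")


def make_ceegrid_montage(
    shell: ShellModel,
    side: str = "left",
    ear_azimuth_deg: float = DEFAULTS["ceegrid_ear_azimuth_deg"],
    semi_axis_vertical: float = DEFAULTS["ceegrid_semi_axis_vertical"],
    semi_axis_horizontal: float = DEFAULTS["ceegrid_semi_axis_horizontal"],
    gap_deg: float = DEFAULTS["ceegrid_gap_deg"],
) -> ElectrodeMontage:
    """C-shaped 10-electrode around-ear array.

    Ten electrodes are spaced evenly along an open ellipse in the scalp
    tangent plane at the ear point, the gap (default 90 deg) facing
    anterior, and are then projected radially onto the scalp.  Labels run
    L1..L8 with the posterior L4 position flanked by L4a/L4b (R.. on the
    right), ordered from the anterior-superior tip over the top and down
    the back to the anterior-inferior tip.
    """
    if side not in ("left", "right"):
        raise ValueError(f"side must be 'left' or 'right', got {side!r}")
    if max(semi_axis_vertical, semi_axis_horizontal) >= shell.scalp_radius / 2:
        raise ValueError("semi-axes must be smaller than half the scalp radius")
    az = np.deg2rad(ear_azimuth_deg if side == "left" else -ear_azimuth_deg)
    ear_dir = np.array([np.cos(az), np.sin(az), 0.0])
    ear_pt = shell.center + shell.scalp_radius * ear_dir
    # tangent-plane basis: in-plane anterior direction and global superior
    ant = np.array([1.0, 0.0, 0.0])
    ant = ant - (ant @ ear_dir) * ear_dir
    ant /= np.linalg.norm(ant)
    sup = np.array([0.0, 0.0, 1.0])
    half_gap = np.deg2rad(gap_deg) / 2.0
    t = np.linspace(half_gap, 2.0 * np.pi - half_gap, 10)
    pts = (
        ear_pt[None, :]
        + semi_axis_horizontal * np.cos(t)[:, None] * ant[None, :]
        + semi_axis_vertical * np.sin(t)[:, None] * sup[None, :]
    )
    pts = project_to_scalp(pts, shell)
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    np.fill_diagonal(d, np.inf)
    if d.min() < 2e-3:
        i, j = np.unravel_index(np.argmin(d), d.shape)
        raise ValueError(
            f"electrodes {i} and {j} overlap after projection "
            f"({d.min() * 1e3:.2f} mm apart)"
        )
    prefix = "L" if side == "left" else "R"
    labels = tuple(prefix + s for s in CEEGRID_LABELS)
    return ElectrodeMontage(labels, pts, (side,) * 10)


def make_volume_grid(
    shell: ShellModel,
    spacing: float = DEFAULTS["grid_spacing"],
    margin: float = DEFAULTS["grid_margin"],
) -> VolumeGrid:
    """Axis-aligned cubic lattice of source points with ``|r| <
    inner_radius - margin``, in lexicographic (x, y, z) order."""
    if spacing <= 0:
        raise ValueError("spacing must be positive")
    rmax = shell.inner_radius - margin
    if rmax <= 0:
        raise ValueError("margin leaves no brain volume")
    k = int(np.floor(rmax / spacing))
    ax = np.arange(-k, k + 1) * spacing
    X, Y, Z = np.meshgrid(ax, ax, ax, indexing="ij")
    pts = np.column_stack([X.ravel(), Y.ravel(), Z.ravel()])
    keep = np.linalg.norm(pts, axis=1) < rmax
    pts = pts[keep] + shell.center
    if len(pts) == 0:
        raise ValueError("no grid points survive inside the innermost shell")
    return VolumeGrid(pts, spacing)


def left_lateral_exclusion(min_y: float = DEFAULTS["medial_exclusion_y"]):
    """Exclusion predicate for a left-lateral region of interest: every
    vertex with ``y < min_y`` (the medial strip and the contralateral side)
    is excluded, mirroring the removal of the medial wall from the analysis
    region."""

    def predicate(vertices: np.ndarray) -> np.ndarray:
        return vertices[:, 1] < min_y

    return predicate


def parcellate(
    surface: CorticalSurface,
    n_patches: int,
    exclusion_predicate: Callable[[np.ndarray], np.ndarray] | None = None,
    seed: int = 0,
) -> Parcellation:
    """Partition the non-excluded vertices into ``n_patches`` connected,
    roughly equal-area patches.

    Seeds are picked by farthest-point sampling (graph distance) from a
    seeded random start; patches then grow by breadth-first accretion over
    mesh edges, always extending the patch with the smallest current area,
    which keeps areas balanced.  Deterministic for a fixed seed.
    """
    if n_patches < 1:
        raise ValueError("n_patches must be >= 1")
    verts = surface.mesh.vertices
    excluded = (
        np.zeros(len(verts), dtype=bool)
        if exclusion_predicate is None
        else np.asarray(exclusion_predicate(verts), dtype=bool)
    )
    included = np.flatnonzero(~excluded)
    if len(included) < n_patches:
        raise ValueError(
            f"{len(included)} non-excluded vertices < {n_patches} patches"
        )
    adj = vertex_adjacency(surface.mesh)
    inc_set = ~excluded

    # connected components of the included region
    comp = np.full(len(verts), -1, dtype=np.int64)
    n_comp = 0
    for v in included:
        if comp[v] >= 0:
            continue
        q = deque([v])
        comp[v] = n_comp
        while q:
            u = q.popleft()
            for w in adj[u]:
                if inc_set[w] and comp[w] < 0:
                    comp[w] = n_comp
                    q.append(w)
        n_comp += 1
    if n_comp > n_patches:
        sizes = [int((comp == c).sum()) for c in range(n_comp)]
        raise ValueError(
            f"non-excluded region has {n_comp} connected components "
            f"(sizes {sizes}) but only {n_patches} patches were requested"
        )

    # farthest-point seed sampling (multi-source BFS hop distance);
    # unreached components sit at infinite distance and get seeded first
    rng = np.random.default_rng(seed)
    seeds = [int(included[rng.integers(len(included))])]
    dist = np.full(len(verts), np.inf)
    _bfs_update(dist, seeds[-1], adj, inc_set)
    while len(seeds) < n_patches:
        cand = included[np.argmax(dist[included])]
        seeds.append(int(cand))
        _bfs_update(dist, seeds[-1], adj, inc_set)

    # smallest-area-first breadth-first accretion
    va = surface.vertex_areas
    patch_id = np.full(len(verts), -1, dtype=np.int64)
    areas = np.zeros(n_patches)
    frontiers: list[deque] = []
    heap: list[tuple[float, int]] = []
    for p, s in enumerate(seeds):
        patch_id[s] = p
        areas[p] = va[s]
        fr = deque(sorted(int(w) for w in adj[s] if inc_set[w]))
        frontiers.append(fr)
        heapq.heappush(heap, (areas[p], p))
    n_assigned = len(seeds)
    n_total = len(included)
    while n_assigned < n_total and heap:
        a, p = heapq.heappop(heap)
        if a != areas[p]:
            continue  # stale entry
        fr = frontiers[p]
        v = -1
        while fr:
            cand = fr.popleft()
            if patch_id[cand] < 0:
                v = cand
                break
        if v < 0:
            continue  # patch can no longer grow
        patch_id[v] = p
        areas[p] += va[v]
        n_assigned += 1
        for w in sorted(int(x) for x in adj[v]):
            if inc_set[w] and patch_id[w] < 0:
                fr.append(w)
        heapq.heappush(heap, (areas[p], p))
    if n_assigned < n_total:  # pragma: no cover - components all seeded
        raise RuntimeError("region growing failed to cover the region")
    return Parcellation(patch_id, n_patches, areas * 1e4)  # m^2 -> cm^2


def _bfs_update(dist: np.ndarray, source: int, adj, inc_set) -> None:
    """In-place relax hop distances from a new source over included vertices."""
    dist[source] = 0.0
    q = deque([source])
    while q:
        u = q.popleft()
        for w in adj[u]:
            if inc_set[w] and dist[w] > dist[u] + 1:
                dist[w] = dist[u] + 1
                q.append(w)


# ---------------------------------------------------------------------------
# the assembled default head


@dataclass(frozen=True)
class SyntheticHead:
    """All geometric inputs of one synthetic study head."""

    shell: ShellModel
    cortex: CorticalSurface
    grid: VolumeGrid
    cap: ElectrodeMontage
    grid_left: ElectrodeMontage
    grid_right: ElectrodeMontage
    parcellation: Parcellation
    seed: int

    @property
    def ear_montage(self) -> ElectrodeMontage:
        """The bilateral 20-electrode around-ear montage."""
        return self.grid_left.combined(self.grid_right)


def _jitter_montage(
    montage: ElectrodeMontage, shell: ShellModel, std: float, rng: np.random.Generator
) -> ElectrodeMontage:
    """Perturb electrode positions tangentially (placement variability),
    then re-project onto the scalp."""
    if std <= 0:
        return montage
    pos = montage.positions - shell.center
    r = np.linalg.norm(pos, axis=1, keepdims=True)
    radial = pos / r
    noise = rng.normal(0.0, std, size=pos.shape)
    noise -= (noise * radial).sum(axis=1, keepdims=True) * radial
    return ElectrodeMontage(
        montage.labels,
        project_to_scalp(pos + noise + shell.center, shell),
        montage.side_tag,
    )


def make_default_head(seed: int = 42, **overrides) -> SyntheticHead:
    """Build the default study head.  All randomness (cortical folding,
    parcellation seeds, electrode placement jitter) flows from ``seed``
    through named substreams, so any stage is independently reproducible.
    Keyword overrides accept any key of :data:`DEFAULTS`.
    """
    p = dict(DEFAULTS)
    unknown = set(overrides) - set(p)
    if unknown:
        raise ValueError(f"unknown head parameters: {sorted(unknown)}")
    p.update(overrides)
    ss = np.random.SeedSequence(seed)
    seed_cortex, seed_parcel, seed_jitter = (
        int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)
    )
    shell = make_shell_model(p["shell_radii"], p["shell_conductivities"])
    cortex = make_synthetic_cortex(
        base_radius=p["cortex_base_radius"],
        fold_amplitude=p["cortex_fold_amplitude"],
        fold_degree_band=tuple(p["cortex_fold_degree_band"]),
        subdivision_level=p["cortex_subdivision_level"],
        seed=seed_cortex,
        shell=shell,
    )
    grid = make_volume_grid(shell, p["grid_spacing"], p["grid_margin"])
    rng = np.random.default_rng(seed_jitter)
    cap = _jitter_montage(
        make_cap_montage(shell, p["cap_n_electrodes"], p["cap_min_elevation_deg"]),
        shell,
        p["montage_jitter_std"],
        rng,
    )
    kw = dict(
        ear_azimuth_deg=p["ceegrid_ear_azimuth_deg"],
        semi_axis_vertical=p["ceegrid_semi_axis_vertical"],
        semi_axis_horizontal=p["ceegrid_semi_axis_horizontal"],
        gap_deg=p["ceegrid_gap_deg"],
    )
    grid_left = _jitter_montage(
        make_ceegrid_montage(shell, "left", **kw), shell, p["montage_jitter_std"], rng
    )
    grid_right = _jitter_montage(
        make_ceegrid_montage(shell, "right", **kw), shell, p["montage_jitter_std"], rng
    )
    parcellation = parcellate(
        cortex,
        p["n_patches"],
        left_lateral_exclusion(p["medial_exclusion_y"]),
        seed=seed_parcel,
    )
    return SyntheticHead(
        shell, cortex, grid, cap, grid_left, grid_right, parcellation, seed
    )
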