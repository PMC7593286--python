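import numpy as np
import pytest

from earfield.head import (
    left_lateral_exclusion,
    make_cap_montage,
    make_ceegrid_montage,
    make_shell_model,
    make_synthetic_cortex,
    make_volume_grid,
    parcellate,
    project_to_scalp,
)


class TestShellModel:
    def test_default_three_shell(self):
        s = make_shell_model([0.08, 0.085, 0.092], [0.33, 0.0042, 0.33])
        assert s.n_shells == 3
        assert s.inner_radius == 0.08
        assert s.scalp_radius == 0.092

    def test_homogeneous_sphere_is_valid(self):
        s = make_shell_model([0.08], [0.33])
        assert s.n_shells == 1

    @pytest.mark.parametrize(
        "radii,sig",
        [
            ([0.085, 0.08], [0.33, 0.33]),  # non-increasing radii
            ([0.08, 0.09], [0.33, -0.1]),  # non-positive conductivity
            ([0.08, 0.09], [0.33]),  # length mismatch
        ],
    )
    def test_invalid_models_rejected(self, radii, sig):
        with pytest.raises(ValueError):
            make_shell_model(radii, sig)


class TestSyntheticCortex:
    def test_unperturbed_limit_is_a_sphere(self):
        c = make_synthetic_cortex(0.065, fold_amplitude=0.0, subdivision_level=2)
        r = np.linalg.norm(c.mesh.vertices, axis=1)
        assert np.max(np.abs(r - 0.065)) < 1e-12
        radial = c.mesh.vertices / r[:, None]
        # discrete normals of a coarse icosphere deviate slightly from radial
        assert np.max(np.linalg.norm(c.normals - radial, axis=1)) < 5e-2

    def test_determinism_and_seed_sensitivity(self):
        a = make_synthetic_cortex(seed=11, subdivision_level=2)
        b = make_synthetic_cortex(seed=11, subdivision_level=2)
        c = make_synthetic_cortex(seed=12, subdivision_level=2)
        assert np.array_equal(a.mesh.vertices, b.mesh.vertices)
        assert np.max(np.abs(a.mesh.vertices - c.mesh.vertices)) > 0

    def test_folding_tilts_normals_like_gyri(self):
        # with 15% folding at degrees 8-16 a sizable share of normals
        # deviates strongly from the radial direction
        c = make_synthetic_cortex(
            0.065, 0.15, (8, 16), subdivision_level=3, seed=7
        )
        u = c.mesh.vertices / np.linalg.norm(c.mesh.vertices, axis=1, keepdims=True)
        cosang = np.einsum("ij,ij->i", c.normals, u)
        angles = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
        assert np.mean(angles > 20.0) >= 0.10

    def test_surface_must_stay_inside_innermost_shell(self):
        shell = make_shell_model([0.07, 0.08], [0.33, 0.33])
        with pytest.raises(ValueError, match="radius"):
            make_synthetic_cortex(0.065, 0.15, shell=shell, subdivision_level=2)


class TestCapMontage:
    def test_default_cap(self):
        shell = make_shell_model()
        cap = make_cap_montage(shell, 128)
        assert cap.n_electrodes == 128
        assert len(set(cap.labels)) == 128
        cap.validate_on_scalp(shell)

    def test_quasi_uniform_spacing(self):
        shell = make_shell_model()
        cap = make_cap_montage(shell, 128)
        d = np.linalg.norm(
            cap.positions[:, None] - cap.positions[None, :], axis=-1
        )
        np.fill_diagonal(d, np.inf)
        nn = d.min(axis=1)
        assert nn.std() / nn.mean() < 0.5

    def test_minimal_montage(self):
        cap = make_cap_montage(make_shell_model(), 2)
        assert cap.n_electrodes == 2


class TestCeegridMontage:
    def test_default_left_grid(self):
        shell = make_shell_model()
        g = make_ceegrid_montage(shell, "left")
        assert g.n_electrodes == 10
        g.validate_on_scalp(shell)
        # C opens anterior: the electrode centroid sits posterior of the ear
        assert g.positions[:, 0].mean() < 0
        # all on the left
        assert np.all(g.positions[:, 1] > 0)

    def test_left_right_mirror_symmetry(self):
        shell = make_shell_model()
        left = make_ceegrid_montage(shell, "left")
        right = make_ceegrid_montage(shell, "right")
        mirrored = left.positions * np.array([1.0, -1.0, 1.0])
        assert np.max(np.abs(mirrored - right.positions)) < 1e-9

    def test_vertical_channel_spans_more_than_horizontal(self):
        g = make_ceegrid_montage(make_shell_model(), "left")
        pos = {lab: p for lab, p in zip(g.labels, g.positions)}
        d_vert = np.linalg.norm(pos["L3"] - pos["L6"])
        d_horz = np.linalg.norm(pos["L1"] - pos["L4b"])
        assert d_vert > d_horz

    def test_overlapping_electrodes_rejected(self):
        with pytest.raises(ValueError, match="overlap|semi-axes"):
            make_ceegrid_montage(
                make_shell_model(),
                "left",
                semi_axis_vertical=5e-4,
                semi_axis_horizontal=5e-4,
            )


class TestProjectToScalp:
    def test_radial_scaling(self):
        shell = make_shell_model()
        out = project_to_scalp(np.array([0.0, 0.0, 0.05]), shell)
        assert np.allclose(out, [0.0, 0.0, 0.092])

    def test_idempotent_on_scalp(self):
        shell = make_shell_model()
        p = np.array([0.092, 0.0, 0.0])
        assert np.allclose(project_to_scalp(p, shell), p)

    def test_center_rejected(self):
        with pytest.raises(ValueError):
            project_to_scalp(np.zeros(3), make_shell_model())


def _brute_force_grid_count(r_inner, spacing, margin):
    rmax = r_inner - margin
    k = int(np.floor(rmax / spacing))
    count = 0
    for i in range(-k, k + 1):
        for j in range(-k, k + 1):
            for l in range(-k, k + 1):
                if (i * i + j * j + l * l) * spacing**2 < rmax**2:
                    count += 1
    return count


class TestVolumeGrid:
    @pytest.mark.parametrize(
        "r_inner,spacing", [(0.08, 0.005), (0.08, 0.011), (0.05, 0.007)]
    )
    def test_count_matches_brute_force_lattice(self, r_inner, spacing):
        shell = make_shell_model([r_inner, r_inner + 0.012], [0.33, 0.33])
        g = make_volume_grid(shell, spacing, margin=0.005)
        assert g.n_points == _brute_force_grid_count(r_inner, spacing, 0.005)

    def test_all_points_inside_brain(self):
        shell = make_shell_model()
        g = make_volume_grid(shell, 0.005)
        r = np.linalg.norm(g.points, axis=1)
        assert np.all(r < shell.inner_radius)

    def test_huge_spacing_keeps_center_point(self):
        g = make_volume_grid(make_shell_model(), spacing=0.5)
        assert g.n_points == 1
        assert np.allclose(g.points[0], 0.0)


class TestParcellation:
    def test_single_patch_covers_everything(self):
        c = make_synthetic_cortex(subdivision_level=2, seed=1)
        p = parcellate(c, 1, seed=0)
        assert np.all(p.patch_id == 0)
        assert p.patch_areas[0] == pytest.approx(c.mesh.area() * 1e4, rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_partition_property_over_seeds(self, seed):
        c = make_synthetic_cortex(subdivision_level=2, seed=5)
        excl = left_lateral_exclusion()
        p = parcellate(c, 10, excl, seed=seed)
        included = ~excl(c.mesh.vertices)
        assert np.all(p.patch_id[included] >= 0)
        assert np.all(p.patch_id[~included] == -1)
        assert len(np.unique(p.patch_id[included])) == 10

    def test_patches_are_edge_connected(self):
        from earfield.geometry import vertex_adjacency
        from collections import deque

        c = make_synthetic_cortex(subdivision_level=2, seed=5)
        p = parcellate(c, 6, left_lateral_exclusion(), seed=3)
        adj = vertex_adjacency(c.mesh)
        for patch in range(6):
            verts = set(p.vertices_of(patch).tolist())
            start = next(iter(verts))
            seen = {start}
            q = deque([start])
            while q:
                u = q.popleft()
                for w in adj[u]:
                    if int(w) in verts and int(w) not in seen:
                        seen.add(int(w))
                        q.append(int(w))
            assert seen == verts

    def test_default_patch_areas_are_balanced(self, default_head):
        areas = default_head.parcellation.patch_areas
        assert default_head.parcellation.n_patches == 50
        assert areas.std(ddof=1) / areas.mean() < 0.35

    def test_too_many_patches_rejected(self):
        c = make_synthetic_cortex(subdivision_level=1, seed=0)
        with pytest.raises(ValueError):
            parcellate(c, c.n_vertices + 1, seed=0)

    def test_determinism(self):
        c = make_synthetic_cortex(subdivision_level=2, seed=5)
        a = parcellate(c, 12, left_lateral_exclusion(), seed=9)
        b = parcellate(c, 12, left_lateral_exclusion(), seed=9)
        assert np.array_equal(a.patch_id, b.patch_id)
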