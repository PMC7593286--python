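import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from earfield.forward import LeadField, compute_leadfield
from earfield.head import ElectrodeMontage, make_default_head, parcellate
from earfield.sensitivity import (
    best_pair_amplitude,
    best_pair_histogram,
    enumerate_pairs,
    patch_potentials,
    run_patch_analysis,
    signal_loss_percent,
    summarize_losses,
    whole_surface_map,
)
from earfield.scenarios import DEFAULT_BIPOLAR_CHANNELS


def _montage(n):
    pts = np.zeros((n, 3))
    pts[:, 0] = np.arange(n)
    return ElectrodeMontage(tuple(f"E{i}" for i in range(n)), pts)


class TestEnumeratePairs:
    @pytest.mark.parametrize("n,expected", [(2, 1), (20, 190), (128, 8128)])
    def test_counts(self, n, expected):
        ps = enumerate_pairs(_montage(n))
        assert ps.n_pairs == expected
        assert len(np.unique(ps.pairs, axis=0)) == expected
        assert np.all(ps.pairs[:, 0] < ps.pairs[:, 1])

    def test_lexicographic_order(self):
        ps = enumerate_pairs(_montage(4))
        assert ps.pairs.tolist() == [[0, 1], [0, 2], [0, 3], [1, 2], [1, 3], [2, 3]]


class TestBestPair:
    def test_obvious_maximum(self):
        ps = enumerate_pairs(_montage(3))
        pair, amp = best_pair_amplitude(np.array([1e-6, -1e-6, 0.0]), ps)
        assert pair == (0, 1)
        assert amp == pytest.approx(2e-6)

    def test_constant_potentials_tie_to_first_pair(self):
        ps = enumerate_pairs(_montage(4))
        pair, amp = best_pair_amplitude(np.full(4, 3.3e-7), ps)
        assert pair == (0, 1)
        assert amp == 0.0

    def test_matches_brute_force_on_random_instances(self, rng):
        ps = enumerate_pairs(_montage(12))
        for _ in range(50):
            v = rng.normal(size=12)
            pair, amp = best_pair_amplitude(v, ps)
            best, bp = -1.0, None
            for i in range(12):
                for j in range(i + 1, 12):
                    a = abs(v[i] - v[j])
                    if a > best:
                        best, bp = a, (i, j)
            assert pair == bp
            assert amp == pytest.approx(best)

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_best_amplitude_bounds_any_fixed_pair(self, seed):
        v = np.random.default_rng(seed).normal(size=8)
        ps = enumerate_pairs(_montage(8))
        _, amp = best_pair_amplitude(v, ps)
        assert amp >= abs(v[2] - v[5]) - 1e-15
        assert amp == pytest.approx(v.max() - v.min())


def _toy_leadfield(n_ch, n_src, rng, labels=None):
    m = rng.normal(size=(n_ch, n_src))
    m -= m.mean(axis=0, keepdims=True)
    labels = labels or tuple(f"E{i}" for i in range(n_ch))
    return LeadField(
        m, labels, rng.normal(size=(n_src, 3)) * 0.01, rng.normal(size=(n_src, 3))
    )


@pytest.fixture(scope="module")
def small():
    head = make_default_head(
        5, cortex_subdivision_level=2, cap_n_electrodes=16, n_patches=6,
        grid_spacing=0.02,
    )
    lf = compute_leadfield(head.cap, head.cortex, head.shell)
    return head, lf


class TestPatchPotentials:
    def test_singleton_patch_equals_scaled_column(self, rng):
        lf = _toy_leadfield(6, 10, rng)
        pid = np.full(10, -1)
        pid[3] = 0
        from earfield.head import Parcellation

        parc = Parcellation(pid, 1, np.array([1.0]))
        v = patch_potentials(lf, parc, 0, amplitude=2e-9)
        assert np.allclose(v, lf.matrix[:, 3] * 2e-9)

    def test_disjoint_patches_sum_to_union(self, small):
        head, lf = small
        parc = head.parcellation
        v0 = patch_potentials(lf, parc, 0)
        v1 = patch_potentials(lf, parc, 1)
        union = np.union1d(parc.vertices_of(0), parc.vertices_of(1))
        v_union = lf.matrix[:, union].sum(axis=1) * 1e-9
        assert np.allclose(v0 + v1, v_union, rtol=1e-12)

    def test_matches_direct_forward_summation(self, small, rng):
        # oracle: sum per-dipole forward solutions without the lead field
        from earfield.forward import Dipole, apply_average_reference, potential_sphere

        head, lf = small
        verts = rng.choice(head.cortex.n_vertices, size=5, replace=False)
        pid = np.full(head.cortex.n_vertices, -1)
        pid[verts] = 0
        from earfield.head import Parcellation

        parc = Parcellation(pid, 1, np.array([1.0]))
        v = patch_potentials(lf, parc, 0, amplitude=1e-9)
        direct = np.zeros(head.cap.n_electrodes)
        for vi in verts:
            direct += potential_sphere(
                Dipole(
                    head.cortex.mesh.vertices[vi],
                    head.cortex.normals[vi] * 1e-9,
                ),
                head.shell,
                head.cap.positions,
            )
        direct = apply_average_reference(direct)
        assert np.allclose(v, direct, rtol=1e-6, atol=1e-15)

    def test_unknown_patch_rejected(self, small):
        head, lf = small
        with pytest.raises(KeyError):
            patch_potentials(lf, head.parcellation, 99)


class TestSignalLoss:
    def test_examples(self):
        assert signal_loss_percent(1.0, 1.0) == 0.0
        assert signal_loss_percent(0.0, 1.0) == 100.0
        assert signal_loss_percent(1.2, 1.0) == pytest.approx(-20.0)

    def test_zero_cap_rejected(self):
        with pytest.raises(ValueError):
            signal_loss_percent(1.0, 0.0)


class TestPatchAnalysis:
    def test_self_comparison_has_zero_loss(self, rng):
        lf = _toy_leadfield(10, 30, rng)
        pid = np.repeat(np.arange(5), 6)
        from earfield.head import Parcellation

        parc = Parcellation(pid, 5, np.ones(5))
        tab = run_patch_analysis(lf, lf, parc)
        assert np.allclose(tab["loss_pct"], 0.0, atol=1e-12)

    def test_summary_mean_is_arithmetic_mean(self, rng):
        lf_cap = _toy_leadfield(10, 30, rng)
        lf_ear = _toy_leadfield(4, 30, rng)
        pid = np.repeat(np.arange(5), 6)
        from earfield.head import Parcellation

        parc = Parcellation(pid, 5, np.ones(5))
        tab = run_patch_analysis(lf_cap, lf_ear, parc)
        s = summarize_losses(tab)
        row = s[s.channel == "ear_grid"].iloc[0]
        assert row["mean"] == pytest.approx(tab["loss_pct"].mean())

    def test_grid_dominates_any_fixed_bipolar_channel(self, leadfields, default_head):
        # max over all 190 pairs >= any named pair, patch by patch (exact)
        lf_cap, lf_ear = leadfields
        tab = run_patch_analysis(
            lf_cap, lf_ear, default_head.parcellation, DEFAULT_BIPOLAR_CHANNELS
        )
        for name in DEFAULT_BIPOLAR_CHANNELS:
            assert np.all(
                tab["loss_pct"] <= tab[f"loss_pct_{name}"] + 1e-9
            )

    def test_scale_invariance_of_loss(self, rng):
        lf_cap = _toy_leadfield(10, 30, rng)
        lf_ear = _toy_leadfield(4, 30, rng)
        pid = np.repeat(np.arange(5), 6)
        from earfield.head import Parcellation

        parc = Parcellation(pid, 5, np.ones(5))
        t1 = run_patch_analysis(lf_cap, lf_ear, parc, amplitude=1e-9)
        t2 = run_patch_analysis(lf_cap, lf_ear, parc, amplitude=7.3e-8)
        assert np.allclose(t1["loss_pct"], t2["loss_pct"], atol=1e-12)
        assert np.allclose(
            t2["cap_amp_nV"], t1["cap_amp_nV"] * 73.0, rtol=1e-12
        )


class TestHistogram:
    def _table(self, pairs, losses):
        return pd.DataFrame(
            {"ear_pair_idx": pairs, "loss_pct": losses}
        )

    def test_concentration_on_single_pair(self):
        m = _montage(4)
        tab = self._table([(0, 1)] * 4 + [(2, 3)], [10, 20, 30, 40, 200])
        h = best_pair_histogram(tab, m)
        # patches below the mean loss (60): the four (0,1) wins
        assert h.counts[0, 1] == 4
        assert h.total == 4

    def test_count_conservation(self, rng):
        m = _montage(6)
        pairs = [tuple(sorted(rng.choice(6, 2, replace=False))) for _ in range(20)]
        losses = rng.uniform(0, 100, 20)
        h = best_pair_histogram(self._table(pairs, losses), m)
        assert h.total == int((losses < losses.mean()).sum())

    def test_empty_inclusion_warns(self, caplog):
        m = _montage(3)
        tab = self._table([], [])
        with caplog.at_level("WARNING"):
            h = best_pair_histogram(tab, m)
        assert h.total == 0


class TestWholeSurfaceMap:
    def test_self_comparison_is_zero_everywhere(self, leadfields, default_head):
        lf_cap, _ = leadfields
        m = whole_surface_map(lf_cap, lf_cap, default_head.cortex)
        assert np.allclose(m.loss_pct, 0.0, atol=1e-12)
        assert m.n_gain == 0

    def test_map_covers_surface_and_is_bounded(self, leadfields, default_head):
        lf_cap, lf_ear = leadfields
        m = whole_surface_map(lf_cap, lf_ear, default_head.cortex)
        assert len(m.loss_pct) == default_head.cortex.n_vertices
        assert np.all(m.loss_pct <= 100.0)

    def test_monotonicity_in_montage_size(self, leadfields, default_head):
        # dropping electrodes from the ear montage can only increase loss
        lf_cap, lf_ear = leadfields
        full = whole_surface_map(lf_cap, lf_ear, default_head.cortex)
        sub = LeadField(
            lf_ear.matrix[:10] - lf_ear.matrix[:10].mean(axis=0, keepdims=True),
            lf_ear.channel_labels[:10],
            lf_ear.source_positions,
            lf_ear.source_orientations,
        )
        reduced = whole_surface_map(lf_cap, sub, default_head.cortex)
        assert np.all(full.loss_pct <= reduced.loss_pct + 1e-9)
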