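"""Windowed connectivity, temporal edge statistics and category contrasts."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dynconn as dc
from dynconn.dfc import CATEGORIES


def brute_force_pearson(x, y):
    x = x - x.mean()
    y = y - y.mean()
    return float((x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum()))


class TestWindowCount:
    def test_full_scan_scheme(self):
        # 883 retained volumes, 155-sample window, unit step -> 729 windows
        assert dc.window_count(883, dc.SlidingWindowSpec(155, 1)) == 729

    def test_single_window_when_length_equals_series(self):
        assert dc.window_count(155, dc.SlidingWindowSpec(155, 7)) == 1

    def test_strided_enumeration(self):
        # onsets 0, 3, 6 for n=10, L=4, step=3
        assert dc.window_count(10, dc.SlidingWindowSpec(4, 3)) == 3

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError, match="invalid window"):
            dc.window_count(100, dc.SlidingWindowSpec(155, 1))

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(n=st.integers(10, 500), length=st.integers(3, 100), step=st.integers(1, 20))
    def test_matches_onset_enumeration(self, n, length, step):
        if length > n:
            return
        onsets = list(range(0, n - length + 1, step))
        assert dc.window_count(n, dc.SlidingWindowSpec(length, step)) == len(onsets)

    def test_seconds_to_samples(self):
        assert dc.window_samples_from_seconds(100.0, 0.645) == 155
        assert dc.window_samples_from_seconds(50.0, 0.645) == 78
        assert dc.window_samples_from_seconds(150.0, 0.645) == 233


class TestSlidingWindowDfc:
    def test_matches_per_window_oracle(self):
        rng = np.random.default_rng(0)
        ts = dc.RegionalTimeSeries(rng.standard_normal((6, 3)), 1.0)
        dfc = dc.sliding_window_dfc(ts, dc.SlidingWindowSpec(4, 1))
        assert dfc.n_windows == 3
        for t, onset in enumerate(dfc.window_onsets):
            seg = ts.values[onset:onset + 4]
            for i in range(3):
                for j in range(i + 1, 3):
                    expect = brute_force_pearson(seg[:, i], seg[:, j])
                    assert dfc.matrices[t][i, j] == pytest.approx(expect, abs=1e-12)
                    assert dfc.matrices[t][j, i] == dfc.matrices[t][i, j]

    def test_identical_and_negated_columns(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(20)
        values = np.stack([base, base, -base], axis=1)
        ts = dc.RegionalTimeSeries(values, 1.0)
        dfc = dc.sliding_window_dfc(ts, dc.SlidingWindowSpec(5, 5))
        assert np.allclose(dfc.matrices[:, 0, 1], 1.0)
        assert np.allclose(dfc.matrices[:, 0, 2], -1.0)

    def test_affine_invariance(self):
        rng = np.random.default_rng(2)
        values = rng.standard_normal((60, 5))
        ts = dc.RegionalTimeSeries(values, 1.0)
        scaled = dc.RegionalTimeSeries(values * [2.0, 0.5, 3.0, 1.0, 10.0] + 7.0, 1.0)
        spec = dc.SlidingWindowSpec(20, 10)
        a = dc.sliding_window_dfc(ts, spec).matrices
        b = dc.sliding_window_dfc(scaled, spec).matrices
        assert np.allclose(a, b, atol=1e-12)

    def test_constant_region_fails_fast_with_context(self):
        values = np.ones((30, 3))
        values[:, 0] = np.arange(30)
        values[:, 2] = np.random.default_rng(0).standard_normal(30)
        ts = dc.RegionalTimeSeries(values, 1.0)
        with pytest.raises(ValueError, match="region 1"):
            dc.sliding_window_dfc(ts, dc.SlidingWindowSpec(10, 1))

    def test_entries_bounded_and_symmetric(self, dfc_series):
        m = dfc_series.matrices
        assert np.all(m <= 1.0 + 1e-12) and np.all(m >= -1.0 - 1e-12)
        assert np.allclose(m, np.transpose(m, (0, 2, 1)))


class TestStaticFc:
    def test_matches_brute_force(self):
        rng = np.random.default_rng(3)
        ts = dc.RegionalTimeSeries(rng.standard_normal((8, 3)), 1.0)
        sfc = dc.static_fc(ts)
        for i in range(3):
            for j in range(3):
                if i != j:
                    expect = brute_force_pearson(ts.values[:, i], ts.values[:, j])
                    assert sfc[i, j] == pytest.approx(expect, abs=1e-12)

    def test_equals_single_full_window(self):
        rng = np.random.default_rng(4)
        ts = dc.RegionalTimeSeries(rng.standard_normal((40, 4)), 1.0)
        dfc = dc.sliding_window_dfc(ts, dc.SlidingWindowSpec(40, 1))
        assert np.allclose(dc.static_fc(ts), dfc.matrices[0])

    def test_region_permutation_relabels_consistently(self):
        rng = np.random.default_rng(5)
        values = rng.standard_normal((30, 5))
        perm = np.array([3, 0, 4, 1, 2])
        a = dc.static_fc(dc.RegionalTimeSeries(values, 1.0))
        b = dc.static_fc(dc.RegionalTimeSeries(values[:, perm], 1.0))
        assert np.allclose(b, a[np.ix_(perm, perm)])


class TestFisherZ:
    def test_fixed_point_and_closed_form(self):
        assert dc.fisher_z(0.0) == 0.0
        assert dc.fisher_z(0.5) == pytest.approx(np.arctanh(0.5))
        assert dc.fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_odd_function(self):
        r = np.linspace(-0.99, 0.99, 21)
        assert np.allclose(dc.fisher_z(-r), -dc.fisher_z(r))

    def test_domain_error_without_clipping(self):
        with pytest.raises(ValueError):
            dc.fisher_z(np.array([1.0]), clip=False)
        assert np.isfinite(dc.fisher_z(np.array([1.0]), clip=True)).all()


class TestSpatialSimilarity:
    def test_self_similarity_and_sign_flip(self):
        rng = np.random.default_rng(6)
        ts = dc.RegionalTimeSeries(rng.standard_normal((50, 6)), 1.0)
        sfc = dc.static_fc(ts)
        dfc = dc.sliding_window_dfc(ts, dc.SlidingWindowSpec(50, 1))
        assert dc.spatial_similarity(sfc, dfc)[0] == pytest.approx(1.0)
        neg = dc.DFCSeries(matrices=-dfc.matrices, window_onsets=dfc.window_onsets,
                           spec=dfc.spec)
        assert dc.spatial_similarity(sfc, neg)[0] == pytest.approx(-1.0)

    def test_preset_similarity_regime(self, bold, dfc_series):
        # D-FC matrices stay highly similar to the static pattern
        sim = dc.spatial_similarity(dc.static_fc(bold), dfc_series)
        assert sim.mean() > 0.7


class TestTemporalEdgeStats:
    def test_hand_evaluated_mean_and_variance(self):
        series = np.array([0.2, 0.4, 0.6])[:, None, None] * np.ones((3, 2, 2))
        dfc = dc.DFCSeries(series, np.arange(3), dc.SlidingWindowSpec(4, 1))
        stats = dc.temporal_edge_stats(dfc)
        assert stats.strength[0, 1] == pytest.approx(0.4, abs=1e-12)
        assert stats.variability[0, 1] == pytest.approx(0.04, abs=1e-12)

    def test_constant_series_zero_variability(self):
        series = 0.5 * np.ones((5, 3, 3))
        dfc = dc.DFCSeries(series, np.arange(5), dc.SlidingWindowSpec(4, 1))
        stats = dc.temporal_edge_stats(dfc)
        assert stats.strength[0, 2] == pytest.approx(0.5)
        assert stats.variability[0, 2] == 0.0

    def test_translation_invariance_of_variability(self):
        rng = np.random.default_rng(7)
        series = rng.uniform(-0.4, 0.4, size=(10, 3, 3))
        series = (series + np.transpose(series, (0, 2, 1))) / 2
        dfc = dc.DFCSeries(series, np.arange(10), dc.SlidingWindowSpec(4, 1))
        shifted = dc.DFCSeries(series + 0.3, np.arange(10), dc.SlidingWindowSpec(4, 1))
        a = dc.temporal_edge_stats(dfc)
        b = dc.temporal_edge_stats(shifted)
        assert np.allclose(b.strength[0, 1], a.strength[0, 1] + 0.3)
        assert np.allclose(b.variability, a.variability, atol=1e-12)

    def test_agrees_with_two_pass_oracle(self, dfc_series):
        stats = dc.temporal_edge_stats(dfc_series)
        r = dfc_series.matrices[:, 2, 9]
        mean = r.sum() / len(r)
        var = ((r - mean) ** 2).sum() / (len(r) - 1)
        assert stats.strength[2, 9] == pytest.approx(mean, abs=1e-12)
        assert stats.variability[2, 9] == pytest.approx(var, abs=1e-12)

    def test_std_option_is_square_root(self, dfc_series):
        var = dc.temporal_edge_stats(dfc_series, variability="var")
        std = dc.temporal_edge_stats(dfc_series, variability="std")
        assert np.allclose(std.variability, np.sqrt(var.variability))

    def test_single_window_rejected(self):
        dfc = dc.DFCSeries(np.ones((1, 3, 3)), np.arange(1), dc.SlidingWindowSpec(4, 1))
        with pytest.raises(ValueError):
            dc.temporal_edge_stats(dfc)


class TestClassifyEdges:
    def test_aal_scale_combinatorics(self):
        parc = dc.generate_parcellation(45, seed=0)
        cats = dc.classify_edges(parc)
        assert (cats == "homotopic").sum() == 45
        assert (cats == "heterotopic").sum() == 1980
        assert (cats == "intrahemispheric").sum() == 1980

    def test_two_pair_enumeration(self):
        parc = dc.generate_parcellation(2, seed=0)
        cats = dc.classify_edges(parc)
        assert (cats == "homotopic").sum() == 2
        assert (cats == "heterotopic").sum() == 2
        assert (cats == "intrahemispheric").sum() == 2

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(n_pairs=st.integers(2, 30))
    def test_partition_covers_all_pairs(self, n_pairs):
        parc = dc.generate_parcellation(n_pairs, seed=0)
        cats = dc.classify_edges(parc)
        n = 2 * n_pairs
        assert len(cats) == n * (n - 1) // 2
        assert set(np.unique(cats)) <= set(CATEGORIES)


class TestCategoryComparison:
    def test_observed_statistic_depends_only_on_labels(self, preset):
        parc, _ = preset
        cats = dc.classify_edges(parc)
        rng = np.random.default_rng(8)
        values = rng.normal(size=cats.size)
        n = parc.n_regions
        mat = np.zeros((n, n))
        iu, ju = dc.edge_index(n)
        mat[iu, ju] = values
        mat = mat + mat.T
        comps = dc.category_comparison(mat, cats, n_perm=200, seed=0)
        for c in comps:
            a, b = c.pair
            expect = values[cats == a].mean() - values[cats == b].mean()
            assert c.result.observed == pytest.approx(expect)
            assert c.p_adjusted == min(1.0, 3 * c.result.p_value)

    def test_p_value_stable_across_seeds(self, preset):
        parc, _ = preset
        cats = dc.classify_edges(parc)
        rng = np.random.default_rng(9)
        values = rng.normal(size=cats.size)
        values[cats == "homotopic"] += 0.35
        n = parc.n_regions
        mat = np.zeros((n, n))
        iu, ju = dc.edge_index(n)
        mat[iu, ju] = values
        mat = mat + mat.T
        n_perm = 2000
        p1 = dc.category_comparison(mat, cats, n_perm=n_perm, seed=1)[0].result.p_value
        p2 = dc.category_comparison(mat, cats, n_perm=n_perm, seed=2)[0].result.p_value
        tol = 3 * np.sqrt(max(p1, 1 / n_perm) * (1 - p1) / n_perm) + 2 / n_perm
        assert abs(p1 - p2) < tol
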