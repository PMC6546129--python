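import numpy as np
import pytest

from jbabin import (CorrelationSpectrum, JbaParams, SpectraSet,
                    aggregate_intensity, expand_seed, find_seeds,
                    merge_neighbours, run_jba, window_correlations)
from jbabin.errors import ParameterError
from jbabin.io import BinnedSet, Cluster
from jbabin.jba import _AGGS

from conftest import small_peak_set


def brute_force_window_corrs(X, st, cm):
    """Independent oracle: explicit loop over all pairs in each window."""
    from scipy.stats import pearsonr, spearmanr

    n, p = X.shape
    out = []
    for i in range(p - st + 1):
        vals = []
        for a in range(i, i + st):
            for b in range(a + 1, i + st):
                xa, xb = X[:, a], X[:, b]
                if xa.std() == 0 or xb.std() == 0:
                    vals.append(0.0)
                elif cm == "pearson":
                    vals.append(pearsonr(xa, xb).statistic)
                else:
                    vals.append(spearmanr(xa, xb).statistic)
        out.append(np.mean(vals))
    return np.array(out)


class TestWindowCorrelations:
    def test_four_identical_copies_give_rbar_one(self):
        v = np.array([1.0, 3.0, 2.0, 5.0, 4.0])
        s = SpectraSet(np.arange(4) * 0.01 + 1, np.tile(v[:, None], (1, 4)),
                       [f"s{i}" for i in range(5)])
        cs = window_correlations(s, st=4)
        assert len(cs) == 1
        assert cs.r_bar[0] == pytest.approx(1.0, abs=1e-12)

    def test_exact_anticorrelation_gives_minus_one(self):
        v = np.array([1.0, 2.0, 4.0])
        s = SpectraSet(np.array([1.0, 1.01]), np.column_stack([v, -v]),
                       ["a", "b", "c"])
        cs = window_correlations(s, st=2, cm="pearson")
        assert cs.r_bar[0] == pytest.approx(-1.0, abs=1e-12)

    @pytest.mark.parametrize("cm", ["pearson", "spearman"])
    def test_matches_brute_force_oracle(self, cm):
        rng = np.random.default_rng(42)
        X = rng.normal(size=(20, 10))
        s = SpectraSet(np.arange(10) * 0.01 + 1, X, [f"s{i}" for i in range(20)])
        cs = window_correlations(s, st=4, cm=cm)
        np.testing.assert_allclose(cs.r_bar, brute_force_window_corrs(X, 4, cm),
                                   atol=1e-12)

    def test_zero_variance_column_counts_as_zero_correlation(self):
        rng = np.random.default_rng(5)
        X = rng.normal(size=(15, 5))
        X[:, 2] = 7.0
        s = SpectraSet(np.arange(5) * 0.01 + 1, X, [f"s{i}" for i in range(15)])
        cs = window_correlations(s, st=3)
        np.testing.assert_allclose(cs.r_bar, brute_force_window_corrs(X, 3, "pearson"),
                                   atol=1e-12)

    def test_window_larger_than_axis_rejected(self):
        s = SpectraSet(np.array([1.0, 1.01]), np.random.default_rng(0).normal(size=(5, 2)),
                       [f"s{i}" for i in range(5)])
        with pytest.raises(ParameterError):
            window_correlations(s, st=3)


class TestFindSeeds:
    def _cs(self, values):
        v = np.asarray(values, dtype=float)
        return CorrelationSpectrum(np.arange(v.size) * 0.01, v, st=4, cm="pearson")

    def test_constant_below_threshold_yields_no_seeds(self):
        assert find_seeds(self._cs([0.5] * 10), ct=0.834) == []

    def test_two_isolated_maxima(self):
        seeds = find_seeds(self._cs([0.2, 0.9, 0.3, 0.95, 0.4]), ct=0.834)
        assert seeds == [1, 3]  # anchors 2 and 4 in 1-based terms

    def test_plateau_yields_single_seed_at_lowest_ppm_anchor(self):
        seeds = find_seeds(self._cs([0.1, 0.9, 0.9, 0.9, 0.2]), ct=0.5)
        assert seeds == [1]

    def test_edge_maximum_compared_to_single_neighbour(self):
        assert find_seeds(self._cs([0.95, 0.4, 0.3]), ct=0.5) == [0]
        assert find_seeds(self._cs([0.3, 0.4, 0.95]), ct=0.5) == [2]

    def test_raising_ct_never_increases_seed_count(self):
        rng = np.random.default_rng(9)
        cs = self._cs(rng.uniform(-1, 1, 200))
        counts = [len(find_seeds(cs, ct)) for ct in np.linspace(-1, 1, 21)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestExpandSeed:
    def test_anticorrelated_flanks_keep_cluster_at_st(self):
        rng = np.random.default_rng(1)
        base = rng.normal(size=30)
        X = np.column_stack([-base + 0.01 * rng.normal(size=30),
                             base, base, base, base,
                             -base + 0.01 * rng.normal(size=30)])
        s = SpectraSet(np.arange(6) * 0.01 + 1, X, [f"s{i}" for i in range(30)])
        p = JbaParams(ct=0.8, st=4)
        cl = expand_seed(s, 1, p)
        assert (cl.start_idx, cl.end_idx) == (1, 4)

    def test_isolated_noiseless_peak_is_covered_exactly(self):
        # a 12-variable Lorentzian driven by concentrations varying x(0.5-2),
        # no noise on the peak itself; flanks are pure independent noise
        rng = np.random.default_rng(0)
        n, nv = 80, 50
        conc = rng.uniform(0.5, 2.0, n)
        shape = 1.0 / (1.0 + ((np.arange(12) - 5.5) / 2.0) ** 2)
        X = 0.3 * rng.normal(size=(n, nv))
        X[:, 19:31] = 80.0 * np.outer(conc, shape)
        s = SpectraSet(np.arange(nv) * 0.002 + 1, X, [f"s{i}" for i in range(n)])
        p = JbaParams(ct=0.8, st=4)
        cs = window_correlations(s, 4)
        best = max(find_seeds(cs, p.ct), key=lambda a: cs.r_bar[a])
        cl = expand_seed(s, best, p)
        assert (cl.start_idx, cl.end_idx) == (19, 30)

    def test_seed_at_first_window_grows_downfield_only(self):
        v = np.random.default_rng(3).normal(size=25)
        X = np.tile(v[:, None], (1, 8))
        s = SpectraSet(np.arange(8) * 0.01 + 1, X, [f"s{i}" for i in range(25)])
        cl = expand_seed(s, 0, JbaParams(ct=0.5, st=4))
        assert cl.start_idx == 0
        assert cl.end_idx == 7  # copies: growth runs to the axis end

    def test_occupied_seed_window_is_dropped(self):
        v = np.random.default_rng(3).normal(size=25)
        X = np.tile(v[:, None], (1, 8))
        s = SpectraSet(np.arange(8) * 0.01 + 1, X, [f"s{i}" for i in range(25)])
        occupied = np.zeros(8, dtype=bool)
        occupied[5] = True
        assert expand_seed(s, 3, JbaParams(ct=0.5, st=4), occupied) is None

    def test_growth_stops_at_claimed_variables(self):
        v = np.random.default_rng(3).normal(size=25)
        X = np.tile(v[:, None], (1, 10))
        s = SpectraSet(np.arange(10) * 0.01 + 1, X, [f"s{i}" for i in range(25)])
        occupied = np.zeros(10, dtype=bool)
        occupied[0] = occupied[8] = True
        cl = expand_seed(s, 2, JbaParams(ct=0.5, st=4), occupied)
        assert (cl.start_idx, cl.end_idx) == (1, 7)


class TestAggregateIntensity:
    @pytest.mark.parametrize("agg,expected", [("sum", 6.0), ("median", 2.0),
                                              ("max", 3.0), ("mean", 2.0)])
    def test_statistics_on_three_member_cluster(self, agg, expected):
        X = np.array([[1.0, 2.0, 3.0], [10.0, 20.0, 30.0], [1.0, 1.0, 1.0]])
        s = SpectraSet(np.array([1.0, 1.01, 1.02]), X, ["a", "b", "c"])
        out = aggregate_intensity(s, Cluster(0, 2, r_bar=1.0), agg)
        assert out[0] == expected


def _binned_from_latents(rng, latents, sizes, agg="sum"):
    """Spectra whose consecutive blocks are rank-1 in the given latent vectors."""
    n = latents.shape[0]
    cols, clusters, start = [], [], 0
    for lat, k in zip(latents.T, sizes):
        block = np.outer(lat, rng.uniform(0.5, 2.0, k))
        block += 0.001 * rng.normal(size=block.shape)
        cols.append(block)
        clusters.append(Cluster(start, start + k - 1, r_bar=0.99))
        start += k
    X = np.concatenate(cols, axis=1)
    ppm = np.arange(X.shape[1]) * 0.01 + 1
    s = SpectraSet(ppm, X, [f"s{i}" for i in range(n)])
    Y = np.column_stack([_AGGS[agg](X[:, c.members], axis=1) for c in clusters])
    return s, BinnedSet(clusters, Y, "JBA", {}, ppm, list(s.sample_ids))


class TestMergeNeighbours:
    def test_common_latent_concentration_merges(self):
        rng = np.random.default_rng(0)
        lat = rng.lognormal(size=100)
        s, b = _binned_from_latents(rng, np.column_stack([lat, lat]), [4, 5])
        merged = merge_neighbours(s, b, JbaParams(ct=0.5, st=4, merge_r=0.90))
        assert merged.n_clusters == 1
        assert (merged.clusters[0].start_idx, merged.clusters[0].end_idx) == (0, 8)

    def test_independent_concentrations_stay_separate(self):
        rng = np.random.default_rng(1)
        lats = rng.lognormal(size=(200, 2))
        s, b = _binned_from_latents(rng, lats, [4, 5])
        merged = merge_neighbours(s, b, JbaParams(ct=0.5, st=4, merge_r=0.90))
        assert merged.n_clusters == 2

    def test_chain_of_three_collapses_to_one(self):
        rng = np.random.default_rng(2)
        lat = rng.lognormal(size=150)
        s, b = _binned_from_latents(rng, np.column_stack([lat] * 3), [4, 4, 6])
        merged = merge_neighbours(s, b, JbaParams(ct=0.5, st=4, merge_r=0.90))
        assert merged.n_clusters == 1

    def test_sum_aggregation_is_conserved_by_merging(self):
        rng = np.random.default_rng(3)
        lat = rng.lognormal(size=120)
        s, b = _binned_from_latents(rng, np.column_stack([lat, lat]), [5, 4])
        total_before = b.Y.sum(axis=1)
        merged = merge_neighbours(s, b, JbaParams(ct=0.5, st=4, merge_r=0.90))
        np.testing.assert_allclose(merged.Y.sum(axis=1), total_before, atol=1e-12)


class TestRunJba:
    def test_pure_iid_noise_yields_no_clusters(self):
        rng = np.random.default_rng(7)
        X = rng.normal(size=(200, 500))
        s = SpectraSet(np.arange(500) * 0.002 + 0.4, X, [f"s{i}" for i in range(200)])
        b = run_jba(s, JbaParams(ct=0.834, st=4))
        assert b.n_clusters == 0

    def test_eight_isolated_peaks_recovered_within_one_variable(self):
        from jbabin.synthetic import Peak, SyntheticSpec, generate

        step = 0.002
        centers = [0.6 + 0.12 * k for k in range(8)]
        spec = SyntheticSpec(
            n_samples=300, ppm_lo=0.4, ppm_hi=1.8, step=step,
            peaks=[Peak(c, step, 90.0, k) for k, c in enumerate(centers)],
            n_factors=8, factor_log_sd=0.4, noise_sd=0.4, noise_rho=0.5,
            shift_sd=0.0, seed=10)
        s, truth = generate(spec)
        b = run_jba(s, JbaParams(ct=0.5, st=4))
        assert b.n_clusters == 8
        for cl, pk in zip(b.clusters, truth.peaks):
            assert abs(cl.start_idx - pk.support_start) <= 1
            assert abs(cl.end_idx - pk.support_end) <= 1

    def test_clusters_are_disjoint_contiguous_and_above_threshold(self, plasma, plasma_ct, plasma_jba):
        _, s, _ = plasma
        p, b = plasma_jba
        for a, c in zip(b.clusters, b.clusters[1:]):
            assert c.start_idx > a.end_idx
        for c in b.clusters:
            assert c.n_variables >= p.st
            members = np.asarray(c.members)
            assert np.all(np.diff(np.sort(members)) >= 1)

    def test_spearman_mode_invariant_under_monotone_transforms(self):
        s, _ = small_peak_set(seed=4, n_samples=80, n_vars=50, peak=(25, 3, 60.0))
        p = JbaParams(ct=0.6, st=4, cm="spearman")
        b1 = run_jba(s, p)
        X = s.X.copy()
        # different strictly increasing transform per variable
        X[:, ::3] = np.exp(X[:, ::3] / X.std())
        X[:, 1::3] = X[:, 1::3] ** 3
        X[:, 2::3] = 5.0 * X[:, 2::3] - 2.0
        s2 = SpectraSet(s.ppm, X, list(s.sample_ids))
        b2 = run_jba(s2, p)
        assert [(c.start_idx, c.end_idx) for c in b1.clusters] == \
               [(c.start_idx, c.end_idx) for c in b2.clusters]

    def test_pearson_mode_invariant_under_positive_affine_transforms(self):
        s, _ = small_peak_set(seed=5, n_samples=80, n_vars=50, peak=(25, 3, 60.0))
        p = JbaParams(ct=0.6, st=4, cm="pearson")
        b1 = run_jba(s, p)
        rng = np.random.default_rng(6)
        scale = rng.uniform(0.5, 3.0, s.n_variables)
        shift = rng.normal(size=s.n_variables)
        s2 = SpectraSet(s.ppm, s.X * scale + shift, list(s.sample_ids))
        b2 = run_jba(s2, p)
        assert [(c.start_idx, c.end_idx) for c in b1.clusters] == \
               [(c.start_idx, c.end_idx) for c in b2.clusters]
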