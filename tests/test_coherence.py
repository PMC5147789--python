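import itertools

import numpy as np
import pandas as pd
import pytest

from cohex.coherence import (
    CoherenceError,
    NullThreshold,
    calibrate_threshold,
    coherence_profile,
    compare_ec_groups,
    compute_ec,
    ec_covariate_correlation,
    ec_for_genes,
    ec_percentile_and_call,
    null_ec_distribution,
)
from cohex.datasets import ExpressionMatrix
from cohex.similarity import PairSimilarity
from cohex.simulate import SimulationConfig, simulate_expression


def _pairs(scores_by_pair, genes):
    m = len(genes)
    M = np.full((m, m), np.nan)
    np.fill_diagonal(M, 1.0)
    for (a, b), s in scores_by_pair.items():
        i, j = genes.index(a), genes.index(b)
        M[i, j] = M[j, i] = s
    return PairSimilarity("pcc", genes, M)


class TestCalibrateThreshold:
    def test_percentile_100_is_max(self, null_expr):
        thr_hi = calibrate_threshold(null_expr, "pcc", percentile=100,
                                     n_pairs=2000, seed=0)
        thr_95 = calibrate_threshold(null_expr, "pcc", percentile=95,
                                     n_pairs=2000, seed=0)
        assert thr_hi.value >= thr_95.value

    def test_all_constant_matrix_errors(self):
        expr = ExpressionMatrix(pd.DataFrame(
            np.ones((5, 20)), index=[f"g{i}" for i in range(5)],
            columns=[f"s{i}" for i in range(20)]))
        with pytest.raises(CoherenceError):
            calibrate_threshold(expr, "pcc", n_pairs=500, seed=0)

    def test_requesting_more_pairs_than_exist_uses_all(self, rng):
        expr = ExpressionMatrix(pd.DataFrame(
            rng.standard_normal((6, 20)), index=[f"g{i}" for i in range(6)],
            columns=[f"s{i}" for i in range(20)]))
        thr = calibrate_threshold(expr, "pcc", n_pairs=10 ** 6, seed=0)
        assert thr.n_pairs == 15

    def test_set_level_measure_requires_set_size(self, null_expr):
        with pytest.raises(CoherenceError):
            calibrate_threshold(null_expr, "pcor_shrinkage", n_pairs=100, seed=0)

    def test_deterministic_given_seed(self, null_expr):
        a = calibrate_threshold(null_expr, "pcc", n_pairs=5000, seed=3)
        b = calibrate_threshold(null_expr, "pcc", n_pairs=5000, seed=3)
        assert a.value == b.value


class TestComputeEc:
    GENES = ["a", "b", "c", "d"]

    def test_all_pairs_above_gives_one(self):
        scores = {p: 0.9 for p in itertools.combinations(self.GENES, 2)}
        assert compute_ec(_pairs(scores, self.GENES), 0.5).ec == 1.0

    def test_no_pair_above_gives_zero(self):
        scores = {p: 0.1 for p in itertools.combinations(self.GENES, 2)}
        assert compute_ec(_pairs(scores, self.GENES), 0.5).ec == 0.0

    def test_three_of_six_gives_half(self):
        pairs = list(itertools.combinations(self.GENES, 2))
        scores = {p: (0.9 if i < 3 else 0.1) for i, p in enumerate(pairs)}
        res = compute_ec(_pairs(scores, self.GENES), 0.5)
        assert res.ec == 0.5
        assert res.n_total == 6
        assert res.n_above == 3

    def test_threshold_ties_do_not_count(self):
        scores = {p: 0.5 for p in itertools.combinations(self.GENES, 2)}
        assert compute_ec(_pairs(scores, self.GENES), 0.5).ec == 0.0

    def test_missing_pairs_excluded_from_both_counts(self):
        pairs = list(itertools.combinations(self.GENES, 2))
        scores = {p: 0.9 for p in pairs[:4]}  # two pairs stay NaN
        res = compute_ec(_pairs(scores, self.GENES), 0.5)
        assert res.n_total == 4
        assert res.n_missing == 2
        assert res.ec == 1.0

    def test_measure_mismatch_errors(self):
        scores = {p: 0.9 for p in itertools.combinations(self.GENES, 2)}
        thr = NullThreshold("spearman", "d", 95, 0.5, 100, 0)
        with pytest.raises(CoherenceError):
            compute_ec(_pairs(scores, self.GENES), thr)


class TestNullEcDistribution:
    def test_infinitely_low_threshold_gives_all_ones(self, null_expr):
        thr = NullThreshold("pcc", "null", 95, -np.inf, 0, 0)
        nulls = null_ec_distribution(null_expr, 5, thr, 20, seed=1)
        np.testing.assert_allclose(nulls, 1.0)

    def test_null_mean_matches_false_positive_rate(self, null_expr):
        thr = calibrate_threshold(null_expr, "pcc", n_pairs=20000, seed=2)
        nulls = null_ec_distribution(null_expr, 10, thr, 100, seed=3)
        # per-pair exceedance is 5% by construction of the threshold
        assert np.mean(nulls) == pytest.approx(0.05, abs=0.02)

    def test_same_seed_identical(self, null_expr):
        thr = calibrate_threshold(null_expr, "pcc", n_pairs=5000, seed=2)
        a = null_ec_distribution(null_expr, 6, thr, 10, seed=5)
        b = null_ec_distribution(null_expr, 6, thr, 10, seed=5)
        np.testing.assert_array_equal(a, b)

    def test_oversized_category_errors(self, null_expr):
        thr = NullThreshold("pcc", "null", 95, 0.5, 100, 0)
        with pytest.raises(CoherenceError):
            null_ec_distribution(null_expr, null_expr.n_genes + 1, thr, 5, 0)


class TestEcPercentile:
    def test_above_all_nulls(self):
        pct, high = ec_percentile_and_call(0.9, np.linspace(0, 0.5, 100))
        assert pct == 100.0
        assert high

    def test_at_null_median(self):
        nulls = np.linspace(0, 1, 101)
        pct, high = ec_percentile_and_call(0.5, nulls)
        assert pct == pytest.approx(50.0, abs=1.0)
        assert not high

    def test_zero_ec_with_all_zero_null_mid_tie(self):
        pct, high = ec_percentile_and_call(0.0, np.zeros(100))
        assert pct == 50.0
        assert not high


@pytest.fixture(scope="module")
def two_dataset_profile():
    cfg = SimulationConfig(
        n_genes=300, n_samples_per_dataset={"dsA": 30, "dsB": 30},
        n_pathways=4, pathway_size_range=(10, 10), rho=0.85,
        coherent_in={"pwy0000": ["dsA"], "pwy0001": ["dsA"],
                     "pwy0002": ["dsA", "dsB"], "pwy0003": ["dsA", "dsB"]},
        evidence_noise=0.0, seed=21)
    expr, truth = simulate_expression(cfg)
    from cohex.simulate import simulate_annotations
    cats = simulate_annotations(cfg, truth)
    by_ds = {
        name: expr.subset(samples=expr.sample_meta.index[
            expr.sample_meta.dataset == name].tolist())
        for name in ("dsA", "dsB")
    }
    return coherence_profile(by_ds, cats, "pcc", n_null_pairs=20000,
                             n_randomizations=100, seed=5)


class TestCoherenceProfile:

    def test_dataset_specific_pathways_called_only_where_coherent(
            self, two_dataset_profile):
        t = two_dataset_profile.table.set_index(["category_id", "dataset"])
        assert t.loc[("pwy0000", "dsA"), "high_ec"]
        assert not t.loc[("pwy0000", "dsB"), "high_ec"]
        assert t.loc[("pwy0002", "dsA"), "high_ec"]
        assert t.loc[("pwy0002", "dsB"), "high_ec"]

    def test_union_count_bounds(self, two_dataset_profile):
        prof = two_dataset_profile
        assert prof.union_count >= prof.high_counts.max()
        assert prof.cumulative_recovery.iloc[-1] == prof.union_count
        assert prof.cumulative_recovery.is_monotonic_increasing

    def test_single_dataset_reduces_to_per_category_calls(self, structured_bundle):
        expr = structured_bundle.expression
        cats = structured_bundle.annotations
        prof = coherence_profile({"dsA": expr}, cats, "pcc",
                                 n_null_pairs=10000, n_randomizations=50,
                                 seed=4)
        assert set(prof.table.dataset) == {"dsA"}
        assert len(prof.table) == len(cats)
        assert prof.union_count == prof.high_counts["dsA"]


class TestGroupComparisons:
    def test_identical_groups_no_rejection(self):
        res = compare_ec_groups([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4])
        assert res.p_value > 0.5

    def test_exact_one_sided_enumeration(self):
        # all 3-subsets of {1..6}: only {4,5,6} gives a larger rank sum,
        # so one-sided P(y > x) = 1/C(6,3) = 0.05
        res = compare_ec_groups([4, 5, 6], [1, 2, 3], alternative="greater")
        assert res.p_value == pytest.approx(1 / 20)

    def test_empty_group_missing(self):
        res = compare_ec_groups([], [0.1, 0.2])
        assert np.isnan(res.p_value)

    def test_size_independent_data_has_null_size_correlation(self, rng):
        ecs = rng.random(50)
        sizes = rng.integers(3, 50, 50)
        r, p = ec_covariate_correlation(ecs, sizes)
        assert abs(r) < 0.35


class TestEcInvariance:
    def test_ec_invariant_to_affine_rescaling(self, structured_bundle):
        expr = structured_bundle.expression
        genes = structured_bundle.truth["pwy0000"].members
        thr = calibrate_threshold(expr, "pcc", n_pairs=5000, seed=1)
        scaled = ExpressionMatrix(expr.values * 3.5 + 2.0, "intensity",
                                  expr.sample_meta)
        ec1 = ec_for_genes(expr, genes, "pcc", thr).ec
        ec2 = ec_for_genes(scaled, genes, "pcc", thr).ec
        assert ec1 == ec2
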