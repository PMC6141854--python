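"""Pearson correlation, percentile bootstrap, ranking and profile comparison.

The bootstrap and the exact Wilcoxon are checked against independent
brute-force oracles: full enumeration of all resamples at n = 3, and full
enumeration of all sign assignments for the signed-rank null.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from lesionload import (
    CohortTable,
    PatientRecord,
    bootstrap_ci,
    compare_profiles,
    correlate_features,
    pearson_r,
    rank_top,
    significance,
    wilcoxon_signed_rank,
)
from lesionload.correlation_stats import (
    CorrelationRecord,
    CorrelationTable,
    feature_rng,
)
from lesionload.lesion_load import LoadMatrix


class TestPearson:
    @pytest.mark.parametrize(
        "x,y,expected",
        [
            ([1, 2, 3], [1, 2, 3], 1.0),
            ([1, 2, 3], [3, 2, 1], -1.0),
            ([1, 2, 3, 4], [2, 1, 4, 3], 0.6),  # hand-evaluated product-moment formula
        ],
    )
    def test_known_values(self, x, y, expected):
        assert pearson_r(x, y) == pytest.approx(expected)

    def test_zero_variance_is_undefined(self):
        assert np.isnan(pearson_r([1, 1, 1], [1, 2, 3]))
        assert np.isnan(pearson_r([1, 2, 3], [5, 5, 5]))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            pearson_r([1], [2])
        with pytest.raises(ValueError):
            pearson_r([1, 2, 3], [1, 2])

    def test_matches_scipy_on_random_data(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            x = rng.normal(size=12)
            y = rng.normal(size=12)
            assert pearson_r(x, y) == pytest.approx(stats.pearsonr(x, y).statistic)

    def test_affine_invariance_and_sign_flip(self):
        rng = np.random.default_rng(1)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r = pearson_r(x, y)
        assert -1.0 <= r <= 1.0
        assert pearson_r(3.0 * x + 5.0, y) == pytest.approx(r)
        assert pearson_r(-x, y) == pytest.approx(-r)


def enumerate_bootstrap_ci(x, y, level=0.95):
    """Oracle: exact percentile interval over all n^n equally likely resamples."""
    n = len(x)
    rs = []
    for idx in itertools.product(range(n), repeat=n):
        r = pearson_r(np.asarray(x)[list(idx)], np.asarray(y)[list(idx)])
        if not np.isnan(r):
            rs.append(r)
    alpha = (1 - level) / 2
    return np.quantile(rs, [alpha, 1 - alpha])


class TestBootstrap:
    def test_constant_outcome_is_non_estimable(self):
        res = bootstrap_ci([1, 2, 3, 4], [5, 5, 5, 5], n_boot=200, seed=0)
        assert not res.estimable
        assert res.n_dropped == 200

    def test_perfect_linear_relation_gives_degenerate_interval(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = bootstrap_ci(x, 2 * x + 1, n_boot=500, seed=0)
        assert res.estimable
        assert res.ci_low == pytest.approx(1.0)
        assert res.ci_high == pytest.approx(1.0)

    def test_seed_reproducibility(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=20), rng.normal(size=20)
        a = bootstrap_ci(x, y, seed=123)
        b = bootstrap_ci(x, y, seed=123)
        c = bootstrap_ci(x, y, seed=124)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)
        assert (a.ci_low, a.ci_high) != (c.ci_low, c.ci_high)

    def test_seed_required(self):
        with pytest.raises(ValueError, match="seed"):
            bootstrap_ci([1, 2, 3], [1, 2, 4])

    def test_matches_enumeration_oracle_at_n3(self):
        # all 27 resamples enumerated exactly; Monte-Carlo interval must agree
        x, y = [0.0, 1.0, 2.0], [0.0, 1.0, 3.0]
        lo, hi = enumerate_bootstrap_ci(x, y)
        res = bootstrap_ci(x, y, n_boot=100_000, seed=5)
        assert res.ci_low == pytest.approx(lo, abs=0.02)
        assert res.ci_high == pytest.approx(hi, abs=0.02)

    def test_dropped_fraction_matches_enumeration_at_n2(self):
        # at n=2 only resamples picking both indices have variance: 2 of 4
        res = bootstrap_ci([0.0, 1.0], [0.0, 1.0], n_boot=40_000, seed=11)
        assert res.n_dropped / 40_000 == pytest.approx(0.5, abs=0.02)


class TestSignificance:
    @pytest.mark.parametrize(
        "lo,hi,expected",
        [(0.2, 0.8, True), (-0.1, 0.5, False), (0.0, 0.5, False), (-0.5, -0.2, True),
         (float("nan"), float("nan"), False)],
    )
    def test_zero_exclusion_rule(self, lo, hi, expected):
        assert significance(lo, hi) is expected


def _loads(values, ids, pids, kind="followup_segmentation"):
    return LoadMatrix(
        values=np.asarray(values, dtype=float),
        total_volume_ml=np.asarray(values, dtype=float).sum(axis=1) / 10.0,
        row_ids=pids,
        column_ids=ids,
        delineation_kind=kind,
    )


class TestCorrelateFeatures:
    @pytest.fixture
    def cohort(self):
        scores = [2, 5, 9, 14, 20, 28]
        return CohortTable(
            [PatientRecord(f"p{i}", "3", s, min(6, s // 7)) for i, s in enumerate(scores)]
        )

    def test_feature_identical_to_outcome_is_significant(self, cohort):
        vals = np.zeros((6, 2))
        vals[:, 0] = cohort.outcome("nihss_3m")
        loads = _loads(vals, [1, 2], cohort.patient_ids)
        table = correlate_features(loads, cohort, "nihss_3m", n_boot=200, seed=0)
        rec = table.get(1)
        assert rec.r == pytest.approx(1.0)
        assert rec.significant

    def test_never_lesioned_region_is_undefined(self, cohort):
        vals = np.zeros((6, 1))
        loads = _loads(vals, [1], cohort.patient_ids)
        rec = correlate_features(loads, cohort, "nihss_3m", n_boot=100, seed=0).get(1)
        assert not rec.defined and not rec.significant

    def test_one_record_per_feature_plus_total_volume(self, cohort):
        loads = _loads(np.zeros((6, 3)), [1, 2, 3], cohort.patient_ids)
        table = correlate_features(loads, cohort, "nihss_3m", n_boot=10, seed=0)
        assert len(table) == 4
        assert [r.feature_id for r in table][-1] == "total_volume"

    def test_alignment_failure_is_hard_error(self, cohort):
        loads = _loads(np.zeros((6, 1)), [1], list(reversed(cohort.patient_ids)))
        with pytest.raises(ValueError, match="align"):
            correlate_features(loads, cohort, "nihss_3m", n_boot=10, seed=0)

    def test_per_feature_streams_are_order_independent(self, cohort):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 50, size=(6, 3))
        big = correlate_features(_loads(vals, [1, 2, 3], cohort.patient_ids), cohort,
                                 "nihss_3m", n_boot=300, seed=7)
        small = correlate_features(_loads(vals[:, 1:2], [2], cohort.patient_ids), cohort,
                                   "nihss_3m", n_boot=300, seed=7)
        a, b = big.get(2), small.get(2)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_feature_rng_is_stable(self):
        a = feature_rng(5, "total_volume").integers(0, 1000, 4)
        b = feature_rng(5, "total_volume").integers(0, 1000, 4)
        assert np.array_equal(a, b)


def make_table(rs):
    records = [
        CorrelationRecord(fid, str(fid), r, np.nan, np.nan, False, 0, 0) for fid, r in rs
    ]
    return CorrelationTable(records=records, outcome_name="nihss_3m")


class TestRankTop:
    def test_undefined_excluded_and_ordered(self):
        table = make_table([(1, 0.5), (2, 0.9), (3, float("nan"))])
        assert [r.feature_id for r in rank_top(table, k=2)] == [2, 1]

    def test_ties_broken_by_region_id(self):
        table = make_table([(9, 0.5), (2, 0.5), (5, 0.5)])
        assert [r.feature_id for r in rank_top(table, k=3)] == [2, 5, 9]

    def test_total_volume_ranks_after_tied_regions(self):
        table = make_table([("total_volume", 0.5), (7, 0.5), (3, 0.8)])
        assert [r.feature_id for r in rank_top(table, k=3)] == [3, 7, "total_volume"]

    def test_k_larger_than_defined(self):
        table = make_table([(1, 0.1), (2, float("nan"))])
        assert [r.feature_id for r in rank_top(table, k=10)] == [1]

    def test_k_below_one_rejected(self):
        with pytest.raises(ValueError):
            rank_top(make_table([(1, 0.1)]), k=0)


def brute_force_wilcoxon_p(diffs):
    """Oracle: exact two-sided p by enumerating every sign assignment."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    ranks = stats.rankdata(np.abs(d))
    observed = ranks[d > 0].sum()
    w_all = [
        np.sum(ranks[np.array(signs, dtype=bool)])
        for signs in itertools.product([0, 1], repeat=len(d))
    ]
    w_all = np.asarray(w_all)
    cdf = np.mean(w_all <= observed)
    sf = np.mean(w_all >= observed)
    return min(1.0, 2.0 * min(cdf, sf))


class TestWilcoxon:
    def test_identical_profiles_are_degenerate(self):
        res = compare_profiles([0.1, 0.2, 0.3], [0.1, 0.2, 0.3])
        assert res.degenerate and res.p_value == 1.0 and res.statistic == 0.0

    def test_two_sided_p_symmetric_under_negation(self):
        d = [0.3, -0.1, 0.25, 0.15, -0.4, 0.05]
        assert wilcoxon_signed_rank(d).p_value == pytest.approx(
            wilcoxon_signed_rank([-x for x in d]).p_value
        )

    def test_exact_p_matches_enumeration_for_five_pairs(self):
        d = [1.0, -2.0, 3.0, 4.0, 5.0]
        res = wilcoxon_signed_rank(d)
        assert res.exact
        assert res.p_value == pytest.approx(brute_force_wilcoxon_p(d))

    @pytest.mark.parametrize("seed", range(6))
    def test_exact_p_matches_enumeration_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 12))
        d = np.round(rng.normal(size=n), 1)  # rounding forces occasional ties
        d = d[d != 0]
        if d.size == 0:
            d = np.array([0.5])
        res = wilcoxon_signed_rank(d)
        assert res.exact
        assert res.p_value == pytest.approx(brute_force_wilcoxon_p(d))

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(3)
        d = rng.normal(size=14)
        ours = wilcoxon_signed_rank(d)
        ref = stats.wilcoxon(d, alternative="two-sided", method="exact")
        assert ours.p_value == pytest.approx(ref.pvalue)

    def test_large_sample_uses_normal_approximation(self):
        rng = np.random.default_rng(4)
        d = rng.normal(0.2, 1.0, size=60)
        res = wilcoxon_signed_rank(d)
        assert not res.exact
        ref = stats.wilcoxon(d, correction=True, alternative="two-sided", method="approx")
        assert res.p_value == pytest.approx(ref.pvalue)

    def test_profiles_paired_by_key_and_nan_excluded(self):
        a = {1: 0.5, 2: 0.4, 3: float("nan"), 4: 0.3}
        b = {1: 0.2, 2: 0.1, 3: 0.9, 4: float("nan")}
        res = compare_profiles(a, b)
        assert res.n_pairs == 2
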