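"""Testing machinery: exact tests vs enumeration and scipy, FDR, fold
changes, and the comparison scheme's family structure."""

import itertools

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings
from hypothesis import strategies as st

from uromet.stats import (
    _fold_change_block,
    _rank_sum_block,
    _signed_rank_block,
    bh_fdr,
    median_fold_change,
    run_main_comparisons,
    run_pretests,
    wilcoxon_rank_sum,
    wilcoxon_signed_rank,
)
from uromet.synthetic import EffectTemplate, SimConfig, generate_cohort
from uromet.preprocess import merge_platforms, normalize_osmolality, compute_excretion


def enumerate_signed_rank_p(diffs):
    """Independent oracle: exact two-sided p by enumerating all 2^n sign
    assignments of the ranks of |d|."""
    d = np.asarray(diffs, dtype=float)
    d = d[d != 0]
    n = len(d)
    ranks = scipy.stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    stats = [sum(r for r, s in zip(ranks, signs) if s)
             for signs in itertools.product([False, True], repeat=n)]
    stats = np.asarray(stats)
    lo = np.mean(stats <= w_obs)
    hi = np.mean(stats >= w_obs)
    return min(1.0, 2.0 * min(lo, hi))


def enumerate_rank_sum_p(left, right):
    """Independent oracle: exact two-sided p by enumerating all group
    labelings of the pooled sample."""
    x = np.asarray(left, dtype=float)
    y = np.asarray(right, dtype=float)
    pooled = np.concatenate([x, y])
    ranks = scipy.stats.rankdata(pooled)
    n1 = len(x)
    r_obs = ranks[:n1].sum()
    stats = [sum(ranks[list(idx)])
             for idx in itertools.combinations(range(len(pooled)), n1)]
    stats = np.asarray(stats)
    lo = np.mean(stats <= r_obs)
    hi = np.mean(stats >= r_obs)
    return min(1.0, 2.0 * min(lo, hi))


def stepup_bh(p):
    """Independent oracle: the textbook Benjamini-Hochberg step-up."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


class TestSignedRank:
    def test_all_positive_ranks_give_smallest_two_sided_p(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5])
        assert res.method == "exact"
        assert res.p == pytest.approx(0.0625)

    def test_symmetric_differences_give_p_one(self):
        assert wilcoxon_signed_rank([-2, -1, 1, 2]).p == pytest.approx(1.0)

    def test_all_zero_differences_degenerate_not_error(self):
        res = wilcoxon_signed_rank([0.0, 0.0, 0.0])
        assert res.p == 1.0
        assert "degenerate" in res.flags

    def test_matches_enumeration_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(42)
        for _ in range(50):
            n = rng.integers(3, 9)
            d = rng.normal(size=n)
            assert wilcoxon_signed_rank(d).p == pytest.approx(
                enumerate_signed_rank_p(d), abs=1e-12)

    def test_matches_scipy_exact_and_approx(self):
        rng = np.random.default_rng(1)
        d = rng.normal(size=12)
        assert wilcoxon_signed_rank(d).p == pytest.approx(
            scipy.stats.wilcoxon(d, method="exact").pvalue)
        d_big = rng.normal(size=40)
        assert wilcoxon_signed_rank(d_big).p == pytest.approx(
            scipy.stats.wilcoxon(d_big, method="approx", correction=True).pvalue,
            rel=1e-6)

    def test_block_equals_scalar_path(self):
        rng = np.random.default_rng(3)
        diffs = rng.normal(size=(30, 10))
        diffs[2, 3] = np.nan
        diffs[5, :] = 0.0
        diffs[7, 1] = diffs[7, 2]  # tie among |d| unlikely but force one
        p, n, flags = _signed_rank_block(diffs)
        for i in range(diffs.shape[0]):
            res = wilcoxon_signed_rank(diffs[i])
            assert p[i] == pytest.approx(res.p, abs=1e-12)
            assert n[i] == res.n


class TestRankSum:
    def test_fully_separated_small_groups(self):
        res = wilcoxon_rank_sum([1, 2, 3], [10, 11, 12])
        assert res.method == "exact"
        assert res.p == pytest.approx(0.1)

    def test_identical_groups_give_p_one(self):
        res = wilcoxon_rank_sum([5.0, 5.0, 5.0], [5.0, 5.0, 5.0])
        assert res.p == pytest.approx(1.0)

    def test_too_small_group_is_untestable(self):
        res = wilcoxon_rank_sum([1.0, np.nan, np.nan], [1.0, 2.0, 3.0])
        assert res.method == "untestable"
        assert np.isnan(res.p)

    def test_matches_enumeration_oracle_on_random_fixtures(self):
        rng = np.random.default_rng(7)
        for _ in range(40):
            n1 = int(rng.integers(3, 7))
            n2 = int(rng.integers(3, 13 - n1 + 1))
            x, y = rng.normal(size=n1), rng.normal(size=n2)
            assert wilcoxon_rank_sum(x, y).p == pytest.approx(
                enumerate_rank_sum_p(x, y), abs=1e-12)

    def test_matches_scipy_exact(self):
        rng = np.random.default_rng(9)
        x, y = rng.normal(size=8), rng.normal(size=9)
        ours = wilcoxon_rank_sum(x, y)
        ref = scipy.stats.mannwhitneyu(x, y, method="exact",
                                       alternative="two-sided")
        assert ours.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_block_equals_scalar_path(self):
        rng = np.random.default_rng(5)
        L = rng.normal(size=(25, 8))
        R = rng.normal(size=(25, 9))
        L[3, 0] = np.nan
        R[4, :] = np.nan
        p, n, flags = _rank_sum_block(L, R)
        for i in range(25):
            res = wilcoxon_rank_sum(L[i], R[i])
            assert (np.isnan(p[i]) and np.isnan(res.p)) or \
                p[i] == pytest.approx(res.p, abs=1e-12)


class TestBhFdr:
    def test_single_p_is_unchanged(self):
        np.testing.assert_allclose(bh_fdr([0.05]), [0.05])

    def test_linear_spaced_example(self):
        np.testing.assert_allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]),
                                   [0.04, 0.04, 0.04, 0.04])

    def test_matches_stepup_oracle_on_random_vectors(self):
        rng = np.random.default_rng(11)
        for _ in range(100):
            p = rng.uniform(1e-8, 1.0, size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), stepup_bh(p), atol=1e-12)

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=1, max_size=30),
           st.floats(1e-6, 1.0))
    def test_adding_a_larger_p_never_lowers_any_q(self, base, extra):
        base = sorted(base)
        q0 = bh_fdr(base)
        q1 = bh_fdr(base + [max(max(base), extra)])
        assert (q1[: len(base)] >= q0 - 1e-12).all()
        assert (bh_fdr(base) <= 1.0 + 1e-12).all()

    def test_invalid_pvalues_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.0, 0.5])
        with pytest.raises(ValueError):
            bh_fdr([0.5, np.nan])


class TestMedianFoldChange:
    def test_identity_and_constant_ratio(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert median_fold_change(x, x, paired=True).fc == pytest.approx(1.0)
        assert median_fold_change(x, 2 * x, paired=True).fc == pytest.approx(2.0)

    def test_unpaired_is_ratio_of_group_medians(self):
        res = median_fold_change([2.0, 4.0, 6.0], [9.0, 10.0, 11.0], paired=False)
        assert res.fc == pytest.approx(2.5)

    def test_unpaired_reciprocal_property(self):
        rng = np.random.default_rng(2)
        x = rng.lognormal(size=9)
        y = rng.lognormal(size=7)
        ab = median_fold_change(x, y, paired=False).fc
        ba = median_fold_change(y, x, paired=False).fc
        assert ab * ba == pytest.approx(1.0)

    def test_zero_denominator_flagged_not_raised(self):
        res = median_fold_change([0.0, 0.0, 0.0], [1.0, 2.0, 3.0], paired=False)
        assert "undefined_fc" in res.flags

    def test_block_equals_scalar_path(self):
        rng = np.random.default_rng(8)
        L = rng.lognormal(size=(20, 10))
        R = rng.lognormal(size=(20, 10))
        L[1, 4] = np.nan
        L[2, :] = np.nan
        for paired in (True, False):
            fc, flags = _fold_change_block(L, R, paired)
            for i in range(20):
                ref = median_fold_change(L[i], R[i], paired=paired)
                if np.isnan(ref.fc):
                    assert np.isnan(fc[i])
                else:
                    assert fc[i] == pytest.approx(ref.fc, abs=1e-12)


@pytest.fixture(scope="module")
def small_pipeline_inputs(small_cohort):
    cohort = small_cohort
    merged, _ = merge_platforms(cohort.nmr, cohort.lcms, cohort.duplicate_ids)
    normalized = normalize_osmolality(merged, cohort.samples)
    excretion = compute_excretion(merged, cohort.samples)
    return cohort, normalized, excretion


class TestComparisonScheme:
    def test_family_sizes_match_design(self, small_pipeline_inputs):
        cohort, normalized, excretion = small_pipeline_inputs
        results = run_main_comparisons(normalized, None, excretion,
                                       cohort.samples)
        f = len(normalized.values)
        within = results[results["family"] == "within"]
        between = results[results["family"] == "between"]
        assert len(within) == f * 6
        assert len(between) == f * (3 + 3 + 1)

    def test_pretests_produce_four_families_per_feature(self, small_pipeline_inputs):
        cohort, normalized, _ = small_pipeline_inputs
        results = run_pretests(normalized, None, cohort.samples)
        assert len(results) == 4 * len(normalized.values)
        assert set(results["comparison_id"]).issuperset(
            {"pretest_U00_V1_V2", "pretest_U00_CME_CVE"})

    def test_q_never_below_p(self, small_pipeline_inputs):
        cohort, normalized, excretion = small_pipeline_inputs
        results = run_main_comparisons(normalized, None, excretion,
                                       cohort.samples)
        ok = results["q_fdr"].notna()
        assert (results.loc[ok, "q_fdr"] >= results.loc[ok, "p_raw"] - 1e-12).all()

    def test_results_invariant_under_feature_relabeling(self, small_pipeline_inputs):
        cohort, normalized, _ = small_pipeline_inputs
        shuffled = normalized.with_values(
            normalized.values.iloc[::-1], normalized.basis)
        a = run_main_comparisons(normalized, None, None, cohort.samples)
        b = run_main_comparisons(shuffled, None, None, cohort.samples)
        a = a.sort_values(["feature_id", "comparison_id"]).reset_index(drop=True)
        b = b.sort_values(["feature_id", "comparison_id"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_injected_carryover_effect_is_flagged_by_pretests(self):
        carry = {"carryover_up": EffectTemplate("carryover_up", {"U04": 3.0}),
                 "null": EffectTemplate("null", {})}
        cfg = SimConfig(seed=21, n_subjects=16, n_targeted=20, n_lcms=8,
                        n_shared=0, n_untargeted=10,
                        templates=carry,
                        template_fractions={"carryover_up": 1.0, "null": 0.0})
        cohort = generate_cohort(cfg)
        merged, _ = merge_platforms(cohort.nmr, cohort.lcms, cohort.duplicate_ids)
        normalized = normalize_osmolality(merged, cohort.samples)
        results = run_pretests(normalized, None, cohort.samples)
        u04 = results[results["comparison_id"].str.contains("U00_U04")]
        power = (u04["q_fdr"] < 0.05).mean()
        assert power > 0.8
        baseline = results[results["comparison_id"] == "pretest_U00_CME_CVE"]
        assert (baseline["q_fdr"] < 0.05).mean() < 0.2
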