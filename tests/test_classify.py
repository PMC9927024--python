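"""Relevance taxonomy: joint q/FC criteria, strict boundaries, direction
profiles and Venn overlap arithmetic."""

import numpy as np
import pandas as pd
import pytest

from uromet.classify import (
    DOWN,
    FLAT,
    UP,
    PlatformThresholds,
    RelevanceThresholds,
    call_relevance,
    fc_relevant,
    summarize_venn,
)


def make_results(rows):
    defaults = {"platform_class": "targeted", "family": "within",
                "basis": "osmolality_normalized", "n": 16, "p_raw": 0.001,
                "direction": "up", "flags": ""}
    records = []
    for row in rows:
        rec = dict(defaults)
        rec.update(row)
        rec.setdefault("family",
                       "between" if rec["comparison_id"].startswith("between")
                       else "within")
        records.append(rec)
    return pd.DataFrame(records)


class TestThresholdSemantics:
    def test_targeted_significant_with_relevant_fc_is_responsive(self):
        results = make_results([{"feature_id": "m1", "q_fdr": 0.01,
                                 "median_fc": 1.6,
                                 "comparison_id": "within_CVE_U00_U01"}])
        calls = call_relevance(results).set_index("feature_id")
        assert calls.loc["m1", "exercise_responsive_CVE"]
        assert not calls.loc["m1", "exercise_responsive_CME"]

    def test_fc_inside_bounds_is_not_relevant(self):
        results = make_results([{"feature_id": "m1", "q_fdr": 0.01,
                                 "median_fc": 1.4,
                                 "comparison_id": "within_CVE_U00_U01"}])
        calls = call_relevance(results).set_index("feature_id")
        assert not calls.loc["m1", "exercise_responsive_CVE"]

    def test_untargeted_needs_wider_bounds(self):
        results = make_results([{"feature_id": "u1", "platform_class": "untargeted",
                                 "q_fdr": 0.04, "median_fc": 1.8,
                                 "comparison_id": "within_CVE_U00_U01"}])
        calls = call_relevance(results).set_index("feature_id")
        assert not calls.loc["u1", "exercise_responsive_CVE"]

    @pytest.mark.parametrize("fc,relevant", [
        (1.5, False),            # strict upper bound, targeted
        (1.5 + 1e-9, True),
        (2.0 / 3.0, False),      # strict lower bound is the exact rational 2/3
        (2.0 / 3.0 - 1e-9, True),
    ])
    def test_targeted_fc_bounds_are_strict(self, fc, relevant):
        assert fc_relevant(fc, PlatformThresholds()) is relevant

    def test_q_threshold_is_strict(self):
        results = make_results([{"feature_id": "m1", "q_fdr": 0.05,
                                 "median_fc": 3.0,
                                 "comparison_id": "within_CME_U00_U01"}])
        calls = call_relevance(results).set_index("feature_id")
        assert not calls.loc["m1", "exercise_responsive_CME"]

    def test_excretion_basis_counts_as_intensity_dependent(self):
        results = make_results([{"feature_id": "m1", "q_fdr": 0.01,
                                 "median_fc": 2.6,
                                 "basis": "absolute_excretion",
                                 "comparison_id": "between_U01_excretion"}])
        calls = call_relevance(results).set_index("feature_id")
        assert calls.loc["m1", "intensity_dependent"]

    def test_reciprocal_bounds(self):
        th = RelevanceThresholds()
        assert th.targeted.fc_down == pytest.approx(1 / th.targeted.fc_up)
        assert th.untargeted.fc_down == pytest.approx(1 / th.untargeted.fc_up)


class TestDirectionProfiles:
    def _calls(self, fcs_qs):
        rows = []
        for tp, (fc, q) in fcs_qs.items():
            rows.append({"feature_id": "m1", "q_fdr": q, "median_fc": fc,
                         "comparison_id": f"within_CVE_U00_{tp}"})
        return call_relevance(make_results(rows)).set_index("feature_id")

    def test_transient_increase(self):
        calls = self._calls({"U01": (3.0, 0.001), "U02": (1.1, 0.5),
                             "U03": (1.0, 0.9)})
        assert calls.loc["m1", "direction_CVE"] == UP + FLAT + FLAT

    def test_persistent_decrease(self):
        calls = self._calls({"U01": (0.4, 0.001), "U02": (0.4, 0.001),
                             "U03": (0.5, 0.001)})
        assert calls.loc["m1", "direction_CVE"] == DOWN * 3

    def test_missing_comparison_gives_question_mark(self):
        calls = self._calls({"U01": (3.0, 0.001)})
        assert calls.loc["m1", "direction_CVE"] == UP + "??"


class TestHeuristicRoute:
    def test_candidate_labels_follow_triggers_without_q(self):
        results = make_results([{"feature_id": "u1",
                                 "platform_class": "untargeted",
                                 "q_fdr": np.nan, "median_fc": np.nan,
                                 "comparison_id": "within_CME_U00_U02"}])
        route_map = pd.DataFrame({
            "feature_id": ["u1"], "route": ["heuristic_candidate"],
            "triggers": ["within_CME_U00_U02:fc=4.2;between_U02:fc=3.0"]})
        calls = call_relevance(results, route_map=route_map).set_index("feature_id")
        assert calls.loc["u1", "route"] == "heuristic"
        assert calls.loc["u1", "exercise_responsive_CME"]
        assert calls.loc["u1", "intensity_dependent"]
        assert not calls.loc["u1", "exercise_responsive_CVE"]


class TestMonotonicity:
    def test_tightening_thresholds_never_adds_calls(self, small_cohort):
        from uromet.pipeline import run_study

        loose = run_study(small_cohort.samples, nmr=small_cohort.nmr,
                          lcms=small_cohort.lcms,
                          untargeted=small_cohort.untargeted,
                          duplicate_map=small_cohort.duplicate_ids)
        tight = call_relevance(
            loose.comparisons,
            RelevanceThresholds(
                targeted=PlatformThresholds(0.01, 2.0, 0.5),
                untargeted=PlatformThresholds(0.01, 3.0, 1 / 3)),
            loose.triage)
        for label in ("exercise_responsive_CME", "exercise_responsive_CVE",
                      "intensity_dependent"):
            loose_set = set(loose.calls.loc[
                (loose.calls[label]) & (loose.calls["route"] == "statistical"),
                "feature_id"])
            tight_set = set(tight.loc[
                (tight[label]) & (tight["route"] == "statistical"),
                "feature_id"])
            assert tight_set <= loose_set


class TestVenn:
    def _calls(self, a, b, c):
        ids = sorted(set(a) | set(b) | set(c))
        return pd.DataFrame({
            "feature_id": ids,
            "platform_class": "targeted",
            "exercise_responsive_CME": [f in a for f in ids],
            "exercise_responsive_CVE": [f in b for f in ids],
            "intensity_dependent": [f in c for f in ids],
        })

    def test_basic_set_arithmetic(self):
        counts = summarize_venn(self._calls({"f1", "f2"}, {"f2"}, set()))
        c = dict(zip(counts["region"], counts["count"]))
        assert c["CME_responsive_total"] == 2
        assert c["CVE_responsive_total"] == 1
        assert c["CME_CVE"] == 1
        assert c["CME_only"] == 1
        assert c["all_three"] == 0

    def test_region_counts_sum_to_union(self):
        rng = np.random.default_rng(3)
        ids = [f"f{i}" for i in range(40)]
        a = {f for f in ids if rng.random() < 0.4}
        b = {f for f in ids if rng.random() < 0.4}
        c = {f for f in ids if rng.random() < 0.4}
        counts = dict(zip(*summarize_venn(self._calls(a, b, c)).to_numpy().T))
        region_sum = sum(counts[k] for k in
                         ("CME_only", "CVE_only", "intensity_only", "CME_CVE",
                          "CME_intensity", "CVE_intensity", "all_three"))
        assert region_sum == counts["union"] == len(a | b | c)

    def test_identity_map_deduplicates_cross_platform_features(self):
        calls = self._calls({"nmr_x", "lcms_x"}, set(), set())
        counts = summarize_venn(calls, identity_map={"nmr_x": "X", "lcms_x": "X"})
        c = dict(zip(counts["region"], counts["count"]))
        assert c["CME_responsive_total"] == 1

    def test_empty_calls_give_zero_counts(self):
        counts = summarize_venn(self._calls(set(), set(), set()))
        assert (counts["count"] == 0).all()
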