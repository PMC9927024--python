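"""Relevance classification of comparison results.

A metabolite is *exercise-responsive* for a trial when at least one
within-trial comparison against baseline is statistically significant
(FDR-adjusted q below alpha) with a median fold change beyond the
platform's relevance bounds, and *intensity-dependent* when a
between-trial comparison (on any basis, including excretion) meets the
same joint criterion. Quantitative targeted platforms use the bounds
FC > 1.5 or FC < 2/3; the relative-quantitative untargeted platform uses
the wider bounds FC > 2.0 or FC < 0.5 (reciprocal pairs; comparisons are
strict). Features routed through the heuristic detection-frequency path
carry no q-value and are relevant exactly when the triage flagged them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_tables import COLLECTION_PHASES, TRIALS

__all__ = [
    "PlatformThresholds",
    "RelevanceThresholds",
    "fc_relevant",
    "call_relevance",
    "direction_profile",
    "summarize_venn",
]

#: symbols for the per-trial direction profile over U01..U03
UP, DOWN, FLAT, UNKNOWN = "↑", "↓", "·", "?"


@dataclass(frozen=True)
class PlatformThresholds:
    q_max: float = 0.05
    fc_up: float = 1.5
    fc_down: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        if not (0 < self.fc_down < 1 < self.fc_up):
            raise ValueError("need 0 < fc_down < 1 < fc_up")


@dataclass(frozen=True)
class RelevanceThresholds:
    """Joint significance + fold-change relevance boundaries per platform
    class. The lower bounds are the exact reciprocals of the upper bounds
    (2/3 = 1/1.5 and 0.5 = 1/2)."""

    targeted: PlatformThresholds = field(
        default_factory=lambda: PlatformThresholds(0.05, 1.5, 2.0 / 3.0))
    untargeted: PlatformThresholds = field(
        default_factory=lambda: PlatformThresholds(0.05, 2.0, 0.5))

    def for_class(self, platform_class: str) -> PlatformThresholds:
        if platform_class == "targeted":
            return self.targeted
        if platform_class == "untargeted":
            return self.untargeted
        raise ValueError(f"unknown platform class {platform_class!r}")


def fc_relevant(fc: float, th: PlatformThresholds) -> bool:
    """Strict fold-change relevance: fc > fc_up or fc < fc_down."""
    return bool(np.isfinite(fc) and (fc > th.fc_up or fc < th.fc_down))


def _label_for_comparison(comparison_id: str) -> str | None:
    """Which relevance label a comparison feeds."""
    if comparison_id.startswith("within_CME"):
        return "exercise_responsive_CME"
    if comparison_id.startswith("within_CVE"):
        return "exercise_responsive_CVE"
    if comparison_id.startswith("between"):
        return "intensity_dependent"
    return None


LABELS = ("exercise_responsive_CME", "exercise_responsive_CVE", "intensity_dependent")


def call_relevance(
    results: pd.DataFrame,
    thresholds: RelevanceThresholds | None = None,
    route_map: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Convert main-comparison results (and triage routes) into per-feature
    relevance calls.

    ``results`` is the output of :func:`uromet.stats.run_main_comparisons`
    (columns feature_id, platform_class, family, comparison_id, q_fdr,
    median_fc, ...). ``route_map`` is the triage table for untargeted
    features (columns feature_id, route, triggers); features absent from
    it default to the statistical route. Returns one row per feature with
    the three relevance labels, the selection route, the list of relevant
    comparisons, and the per-trial direction profile over U01..U03.
    """
    thresholds = thresholds or RelevanceThresholds()
    routes: dict[str, str] = {}
    triggers: dict[str, str] = {}
    if route_map is not None:
        for row in route_map.itertuples(index=False):
            routes[row.feature_id] = row.route
            triggers[row.feature_id] = getattr(row, "triggers", "") or ""
    known = {"statistical", "heuristic_candidate", "dropped", "heuristic_pool"}
    bad = {r for r in routes.values() if r not in known}
    if bad:
        raise ValueError(f"unknown routes {sorted(bad)}")

    res = results[results["family"].isin(["within", "between"])].copy()
    per_class = {c: thresholds.for_class(c)
                 for c in res["platform_class"].unique()}
    q_max = res["platform_class"].map(lambda c: per_class[c].q_max)
    fc_up = res["platform_class"].map(lambda c: per_class[c].fc_up)
    fc_down = res["platform_class"].map(lambda c: per_class[c].fc_down)
    q = res["q_fdr"].to_numpy(dtype=float)
    fc = res["median_fc"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        res["relevant"] = (np.isfinite(q) & (q < q_max.to_numpy())
                           & np.isfinite(fc)
                           & ((fc > fc_up.to_numpy()) | (fc < fc_down.to_numpy())))
    route_series = res["feature_id"].map(lambda f: routes.get(f, "statistical"))
    res.loc[route_series != "statistical", "relevant"] = False

    # direction symbols for the within-trial profile
    with np.errstate(invalid="ignore"):
        res["symbol"] = np.where(~res["relevant"], FLAT,
                                 np.where(fc > 1.0, UP, DOWN))

    features = list(dict.fromkeys(results["feature_id"]))
    grouped = res.groupby("feature_id", sort=False)
    rel_ids = grouped.apply(
        lambda g: ";".join(g.loc[g["relevant"], "comparison_id"]),
        include_groups=False).to_dict()
    symbol_lookup = {
        (f, c): s for f, c, s in zip(res["feature_id"], res["comparison_id"],
                                     res["symbol"])}
    label_sets = {name: set() for name in LABELS}
    rel_rows = res[res["relevant"]]
    for f, cid in zip(rel_rows["feature_id"], rel_rows["comparison_id"]):
        label = _label_for_comparison(cid)
        if label:
            label_sets[label].add(f)

    platform_of = dict(zip(results["feature_id"], results["platform_class"]))
    calls = []
    for feature in features:
        route = routes.get(feature, "statistical")
        labels = {name: feature in label_sets[name] for name in LABELS}
        relevant_ids = rel_ids.get(feature, "")
        if route == "heuristic_candidate":
            route = "heuristic"
            ids = []
            for trig in filter(None, triggers.get(feature, "").split(";")):
                comparison_id = trig.split(":", 1)[0]
                ids.append(comparison_id)
                label = _label_for_comparison(comparison_id)
                if label:
                    labels[label] = True
            relevant_ids = ";".join(ids)
        elif route != "statistical":
            route = "dropped"
        profiles = {}
        for trial in TRIALS:
            profiles[trial] = "".join(
                symbol_lookup.get((feature, f"within_{trial}_U00_{tp}"), UNKNOWN)
                for tp in COLLECTION_PHASES)
        calls.append({
            "feature_id": feature,
            "platform_class": platform_of[feature],
            "route": route,
            **labels,
            "relevant_comparisons": relevant_ids,
            "direction_CME": profiles["CME"],
            "direction_CVE": profiles["CVE"],
        })
    return pd.DataFrame(calls)


def direction_profile(
    feature_results: pd.DataFrame, th: PlatformThresholds, trial: str
) -> str:
    """Ordered symbols over (U01, U02, U03) for one trial's within-group
    comparisons: up/down arrow when relevant, a middle dot when tested but
    not relevant, '?' when the comparison is missing."""
    if trial not in TRIALS:
        raise ValueError(f"unknown trial {trial!r}")
    symbols = []
    for tp in COLLECTION_PHASES:
        cid = f"within_{trial}_U00_{tp}"
        row = feature_results[feature_results["comparison_id"] == cid]
        if len(row) == 0:
            symbols.append(UNKNOWN)
            continue
        r = row.iloc[0]
        ok = (np.isfinite(r["q_fdr"]) and r["q_fdr"] < th.q_max
              and fc_relevant(r["median_fc"], th))
        if not ok:
            symbols.append(FLAT)
        elif r["median_fc"] > 1:
            symbols.append(UP)
        else:
            symbols.append(DOWN)
    return "".join(symbols)


VENN_REGIONS = (
    "CME_only", "CVE_only", "intensity_only",
    "CME_CVE", "CME_intensity", "CVE_intensity", "all_three",
)


def summarize_venn(
    calls: pd.DataFrame,
    identity_map: Mapping[str, str] | None = None,
) -> pd.DataFrame:
    """Counts for the 7 regions of the 3-set Venn diagram over
    CME-responsive, CVE-responsive and intensity-dependent features, plus
    per-set totals and the union.

    ``identity_map`` maps feature_id to a metabolite identity so a
    metabolite detected on several platforms is counted once; default is
    the feature_id itself.
    """
    ident = dict(identity_map) if identity_map else {}

    def members(label: str) -> set[str]:
        if len(calls) == 0:
            return set()
        ids = calls.loc[calls[label].astype(bool), "feature_id"]
        return {ident.get(f, f) for f in ids}

    a = members("exercise_responsive_CME")
    b = members("exercise_responsive_CVE")
    c = members("intensity_dependent")
    counts = {
        "CME_only": len(a - b - c),
        "CVE_only": len(b - a - c),
        "intensity_only": len(c - a - b),
        "CME_CVE": len((a & b) - c),
        "CME_intensity": len((a & c) - b),
        "CVE_intensity": len((b & c) - a),
        "all_three": len(a & b & c),
        "CME_responsive_total": len(a),
        "CVE_responsive_total": len(b),
        "intensity_dependent_total": len(c),
        "union": len(a | b | c),
    }
    return pd.DataFrame({"region": list(counts), "count": list(counts.values())})
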