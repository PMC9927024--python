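"""End-to-end orchestration of the crossover analysis.

``run_study`` wires the stages together: platform merge → osmolality
normalization and excretion for targeted metabolites; QC drift correction
→ detection-frequency triage for untargeted features; pre-tests; the main
within-/between-group comparison scheme with pooled FDR families; joint
significance + fold-change relevance classification; Venn and heatmap
summaries; and a machine-readable manifest with per-stage feature counts.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import classify, feature_filter, preprocess, reporting, stats
from .classify import RelevanceThresholds
from .io_tables import (
    MeasurementMatrix,
    SampleRecord,
    ValidationError,
    samples_frame,
    validate_samples,
    write_results,
)

__all__ = ["AnalysisConfig", "StudyResult", "run_study", "write_study_outputs"]


@dataclass
class AnalysisConfig:
    """Tunable analysis parameters (defaults reproduce the standard
    workflow: alpha 0.05 on FDR-adjusted p-values, relevance bounds
    1.5 / 2:3 targeted and 2.0 / 0.5 untargeted, LOWESS span 0.75 over QC
    points, eligibility >50% detection in >=9 of 10 subgroups)."""

    alpha: float = 0.05
    fdr_scope: str = "pooled"  # or "per_comparison"
    paired_targeted: bool = True
    paired_untargeted: bool = False
    drift_span: float = 0.75
    min_qc: int = 5
    eligibility_min_freq: float = 0.5
    eligibility_min_subgroups: int = 9
    heuristic_low: float = 0.30
    heuristic_high: float = 0.75
    heuristic_mode: str = "pair"  # or "any"
    r2_floor: float = 0.87
    targeted_fc_up: float = 1.5
    untargeted_fc_up: float = 2.0

    @property
    def thresholds(self) -> RelevanceThresholds:
        return RelevanceThresholds(
            targeted=classify.PlatformThresholds(
                self.alpha, self.targeted_fc_up, 1.0 / self.targeted_fc_up),
            untargeted=classify.PlatformThresholds(
                self.alpha, self.untargeted_fc_up, 1.0 / self.untargeted_fc_up),
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: Mapping) -> "AnalysisConfig":
        fields = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - fields
        if unknown:
            raise ValidationError(f"unknown analysis config keys {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})


@dataclass
class StudyResult:
    """All intermediate and final artifacts of one analysis run."""

    comparisons: pd.DataFrame
    pretests: pd.DataFrame
    triage: pd.DataFrame | None
    calls: pd.DataFrame
    venn_counts: pd.DataFrame
    heatmap: pd.DataFrame
    merged_targeted: MeasurementMatrix | None
    normalized_targeted: MeasurementMatrix | None
    excretion: pd.DataFrame | None
    corrected_untargeted: MeasurementMatrix | None
    merge_report: pd.DataFrame | None
    drift_report: pd.DataFrame | None
    counts: dict[str, int]
    manifest: dict
    samples: pd.DataFrame | None = None


def run_study(
    samples: Sequence[SampleRecord],
    *,
    nmr: MeasurementMatrix | None = None,
    lcms: MeasurementMatrix | None = None,
    targeted: MeasurementMatrix | None = None,
    untargeted: MeasurementMatrix | None = None,
    feature_meta: pd.DataFrame | None = None,
    duplicate_map: Sequence[str] | Mapping[str, str] | None = None,
    config: AnalysisConfig | None = None,
    seed: int | None = None,
) -> StudyResult:
    """Run the full crossover analysis.

    Targeted input is either the two platform matrices (``nmr`` + ``lcms``
    with ``duplicate_map``) or a pre-merged ``targeted`` matrix; both are
    raw-basis concentration matrices. ``untargeted`` is the raw GC×GC-MS
    intensity matrix including QC injections. Either platform class may be
    omitted. ``seed`` is recorded in the manifest only — the analysis
    itself is deterministic.
    """
    config = config or AnalysisConfig()
    validate_samples(samples)
    sdf = samples_frame(samples)

    merged = merge_report = None
    if targeted is not None:
        merged = targeted
    elif nmr is not None and lcms is not None:
        merged, merge_report = preprocess.merge_platforms(
            nmr, lcms, duplicate_map or [], r2_floor=config.r2_floor)
    elif nmr is not None or lcms is not None:
        raise ValidationError(
            "supply both nmr and lcms matrices (with duplicate_map), "
            "or a pre-merged targeted matrix")

    normalized = excretion = None
    if merged is not None:
        merged.check_samples(samples)
        normalized = preprocess.normalize_osmolality(merged, sdf)
        has_volumes = any(r.urine_volume is not None for r in samples)
        if has_volumes:
            excretion = preprocess.compute_excretion(merged, sdf)

    corrected = drift_report = triage_table = None
    eligible: list[str] | None = None
    if untargeted is not None:
        untargeted.check_samples(samples)
        has_qc = any(r.is_qc for r in samples
                     if r.sample_id in set(untargeted.values.columns))
        if has_qc:
            corrected, drift_report = preprocess.qc_drift_correct(
                untargeted, sdf, span=config.drift_span, min_qc=config.min_qc)
        else:
            corrected = untargeted
        triage_table = feature_filter.triage(
            corrected, sdf,
            min_freq=config.eligibility_min_freq,
            min_subgroups=config.eligibility_min_subgroups,
            low=config.heuristic_low, high=config.heuristic_high,
            fc_up=config.thresholds.untargeted.fc_up,
            fc_down=config.thresholds.untargeted.fc_down,
            mode=config.heuristic_mode)
        eligible = triage_table.loc[triage_table["route"] == "statistical",
                                    "feature_id"].tolist()

    if merged is None and corrected is None:
        raise ValidationError("no measurement matrices supplied")

    pretests = stats.run_pretests(
        normalized, corrected, sdf,
        paired_targeted=config.paired_targeted,
        paired_untargeted=config.paired_untargeted,
        eligible_untargeted=eligible, alpha=config.alpha)
    comparisons = stats.run_main_comparisons(
        normalized, corrected, excretion, sdf,
        paired_targeted=config.paired_targeted,
        paired_untargeted=config.paired_untargeted,
        eligible_untargeted=eligible, fdr_scope=config.fdr_scope)

    calls = classify.call_relevance(comparisons, config.thresholds, triage_table)
    # heuristic candidates have no statistical rows; append their calls
    if triage_table is not None:
        tested = set(calls["feature_id"])
        extra = triage_table[(triage_table["route"] == "heuristic_candidate")
                             & ~triage_table["feature_id"].isin(tested)]
        extra_calls = []
        for row in extra.itertuples(index=False):
            labels = {name: False for name in classify.LABELS}
            rel = []
            for trig in filter(None, row.triggers.split(";")):
                cid = trig.split(":", 1)[0]
                rel.append(cid)
                label = classify._label_for_comparison(cid)
                if label:
                    labels[label] = True
            extra_calls.append({
                "feature_id": row.feature_id, "platform_class": "untargeted",
                "route": "heuristic", **labels,
                "relevant_comparisons": ";".join(rel),
                "direction_CME": "???", "direction_CVE": "???"})
        if extra_calls:
            calls = pd.concat([calls, pd.DataFrame(extra_calls)],
                              ignore_index=True)
        # dropped features appear with all-false labels
        untested = triage_table[(triage_table["route"] == "dropped")
                                & ~triage_table["feature_id"].isin(set(calls["feature_id"]))]
        if len(untested):
            dropped_calls = pd.DataFrame({
                "feature_id": untested["feature_id"],
                "platform_class": "untargeted",
                "route": "dropped",
                **{name: False for name in classify.LABELS},
                "relevant_comparisons": "",
                "direction_CME": "???", "direction_CVE": "???"})
            calls = pd.concat([calls, dropped_calls], ignore_index=True)

    identity_map = None
    if feature_meta is not None:
        identity_map = dict(zip(feature_meta["feature_id"],
                                feature_meta["display_name"]))
    venn_counts = classify.summarize_venn(calls, identity_map)
    heatmap = reporting.zscore_median_matrix(
        normalized, corrected, sdf, calls, feature_meta)

    label_cols = list(classify.LABELS)
    main = comparisons[comparisons["family"].isin(["within", "between"])]
    counts = {
        "n_samples": int((~sdf["is_qc"]).sum()),
        "n_targeted": 0 if merged is None else len(merged.values),
        "n_untargeted_detected": 0 if corrected is None else len(corrected.values),
        "n_statistical_route": 0 if triage_table is None else
            int((triage_table["route"] == "statistical").sum()),
        "n_heuristic_candidates": 0 if triage_table is None else
            int((triage_table["route"] == "heuristic_candidate").sum()),
        "n_dropped": 0 if triage_table is None else
            int((triage_table["route"] == "dropped").sum()),
        "n_significant_features": int(
            main.loc[main["q_fdr"] < config.alpha, "feature_id"].nunique()),
        "n_relevant": int(calls[label_cols].any(axis=1).sum()),
    }
    manifest = reporting.build_manifest(config.to_dict(), seed, counts)
    return StudyResult(
        comparisons=comparisons, pretests=pretests, triage=triage_table,
        calls=calls, venn_counts=venn_counts, heatmap=heatmap,
        merged_targeted=merged, normalized_targeted=normalized,
        excretion=excretion, corrected_untargeted=corrected,
        merge_report=merge_report, drift_report=drift_report,
        counts=counts, manifest=manifest, samples=sdf)


def write_study_outputs(
    result: StudyResult, out_dir: str | os.PathLike, render: bool = True
) -> dict[str, object]:
    """Write the result tables (and figures + manifest) to ``out_dir``."""
    paths: dict[str, object] = dict(write_results(
        result.comparisons, result.calls, out_dir,
        venn_counts=result.venn_counts, heatmap=result.heatmap))
    if result.triage is not None:
        triage_path = os.path.join(str(out_dir), "triage.tsv")
        result.triage.to_csv(triage_path, sep="\t", index=False)
        paths["triage.tsv"] = triage_path
    pre_path = os.path.join(str(out_dir), "pretests.tsv")
    result.pretests.to_csv(pre_path, sep="\t", index=False,
                           float_format="%.9g")
    paths["pretests.tsv"] = pre_path
    rendered = reporting.render_reports(
        out_dir, result.manifest,
        heatmap=result.heatmap if render else None,
        venn_counts=result.venn_counts if render else None,
        triage=result.triage if render else None,
        untargeted=result.corrected_untargeted if render else None,
        samples=result.samples if render else None)
    paths.update(rendered)
    return paths
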