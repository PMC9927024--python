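"""Two-step triage of untargeted spectral features.

Untargeted GC×GC-MS features carry missing values because weak signals
fall below the detection limit, so a feature's detection frequency is
computed in each of the ten (trial, timepoint) subgroups. Features
detected in more than 50% of samples in at least nine of the ten
subgroups enter the statistical route; the remainder are screened
heuristically: a low-frequency feature becomes a review candidate when,
for one of the main subgroup comparisons, detection frequency is below
30% on one side and above 75% on the other while the (imputed) median
fold change between the two subgroups exceeds 2.0 or falls below 0.5.
All frequency and fold-change comparisons are strict, matching the
boundary semantics of the filter. Candidates are destined for human
review via box/line plots; everything else is dropped.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd

from .io_tables import (
    COLLECTION_PHASES,
    TIMEPOINTS,
    TRIALS,
    MeasurementMatrix,
    SampleRecord,
    ValidationError,
    samples_frame,
)
from .stats import main_comparison_scheme

__all__ = [
    "SUBGROUPS",
    "subgroup_label",
    "detection_frequency",
    "statistical_eligibility",
    "heuristic_candidates",
    "triage",
]

#: the ten (trial, timepoint) subgroups, CME first
SUBGROUPS = tuple((trial, tp) for trial in TRIALS for tp in TIMEPOINTS)


def subgroup_label(trial: str, timepoint: str) -> str:
    return f"{trial}:{timepoint}"


def _study_frame(samples) -> pd.DataFrame:
    sdf = samples if isinstance(samples, pd.DataFrame) else samples_frame(samples)
    return sdf[~sdf["is_qc"]]


def detection_frequency(
    matrix: MeasurementMatrix, samples: Sequence[SampleRecord] | pd.DataFrame
) -> pd.DataFrame:
    """Detection frequency (non-missing fraction) per feature and subgroup.

    Returns a feature × 10 DataFrame with columns labelled "CME:U00" ...
    "CVE:U04". Frequencies are exact count ratios over the non-QC samples
    of each subgroup; a subgroup without samples in the matrix is an error.
    """
    sdf = _study_frame(samples)
    detected = matrix.values.notna()
    out = {}
    for trial, tp in SUBGROUPS:
        cols = sdf.loc[(sdf["trial"] == trial) & (sdf["timepoint"] == tp), "sample_id"]
        cols = [c for c in cols if c in detected.columns]
        if not cols:
            raise ValidationError(
                f"subgroup {subgroup_label(trial, tp)} has no samples in the matrix")
        out[subgroup_label(trial, tp)] = detected[cols].mean(axis=1)
    return pd.DataFrame(out)


def statistical_eligibility(
    freq_table: pd.DataFrame,
    min_freq: float = 0.5,
    min_subgroups: int = 9,
) -> pd.DataFrame:
    """First triage step: a feature is eligible for statistics iff its
    detection frequency strictly exceeds ``min_freq`` in at least
    ``min_subgroups`` of the ten subgroups; the rest form the heuristic
    pool."""
    n_above = (freq_table > min_freq).sum(axis=1)
    route = np.where(n_above >= min_subgroups, "statistical", "heuristic_pool")
    return pd.DataFrame({
        "feature_id": freq_table.index,
        "route": route,
        "n_subgroups_detected": n_above.to_numpy(),
    })


def _imputed_values(matrix: MeasurementMatrix, study_cols: list[str]) -> pd.DataFrame:
    """Left-censor imputation: missing cells take half the feature's global
    minimum detected intensity (features never detected stay missing)."""
    vals = matrix.values[study_cols]
    fill = (vals.min(axis=1) / 2.0).to_numpy()
    arr = vals.to_numpy(dtype=float)
    arr = np.where(np.isnan(arr), fill[:, None], arr)
    return pd.DataFrame(arr, index=vals.index, columns=vals.columns)


def heuristic_candidates(
    freq_table: pd.DataFrame,
    matrix: MeasurementMatrix,
    samples: Sequence[SampleRecord] | pd.DataFrame,
    pool: Sequence[str],
    *,
    low: float = 0.30,
    high: float = 0.75,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    mode: str = "pair",
) -> pd.DataFrame:
    """Second triage step on the heuristic pool.

    ``mode='pair'`` (default) tests the two members of each main subgroup
    comparison against the frequency bounds; ``mode='any'`` tests any two
    of the ten subgroups (the comparison pair is then the low/high pair
    itself). The fold change is right/left over all subgroup samples after
    left-censor imputation. Triggering comparisons are recorded as
    "comparison_id:fc=<value>" for the review plots.
    """
    if mode not in ("pair", "any"):
        raise ValueError(f"unknown heuristic mode {mode!r}")
    sdf = _study_frame(samples)
    study_cols = [c for c in matrix.values.columns if c in set(sdf["sample_id"])]
    imputed = _imputed_values(matrix, study_cols)
    subgroup_cols = {
        subgroup_label(t, u): [
            c for c in sdf.loc[(sdf["trial"] == t) & (sdf["timepoint"] == u),
                               "sample_id"] if c in imputed.columns]
        for t, u in SUBGROUPS
    }
    if mode == "pair":
        pairs = [
            (subgroup_label(*spec.left), subgroup_label(*spec.right), spec.comparison_id)
            for spec in main_comparison_scheme(paired=False, basis=matrix.basis)
        ]
    else:
        labels = [subgroup_label(t, u) for t, u in SUBGROUPS]
        pairs = [(a, b, f"{a}|{b}") for i, a in enumerate(labels)
                 for b in labels[i + 1:]]
    rows = []
    for feature in pool:
        freqs = freq_table.loc[feature]
        vals = imputed.loc[feature]
        trigs = []
        for left, right, cid in pairs:
            fl, fr = freqs[left], freqs[right]
            if not ((fl < low and fr > high) or (fr < low and fl > high)):
                continue
            lv = vals[subgroup_cols[left]].to_numpy(dtype=float)
            rv = vals[subgroup_cols[right]].to_numpy(dtype=float)
            lv, rv = lv[~np.isnan(lv)], rv[~np.isnan(rv)]
            if lv.size == 0 or rv.size == 0 or np.median(lv) == 0:
                continue
            fc = float(np.median(rv) / np.median(lv))
            if fc > fc_up or fc < fc_down:
                trigs.append(f"{cid}:fc={fc:.4g}")
        rows.append({
            "feature_id": feature,
            "route": "heuristic_candidate" if trigs else "dropped",
            "triggers": ";".join(trigs),
        })
    return pd.DataFrame(rows, columns=["feature_id", "route", "triggers"])


def triage(
    matrix: MeasurementMatrix,
    samples: Sequence[SampleRecord] | pd.DataFrame,
    *,
    min_freq: float = 0.5,
    min_subgroups: int = 9,
    low: float = 0.30,
    high: float = 0.75,
    fc_up: float = 2.0,
    fc_down: float = 0.5,
    mode: str = "pair",
) -> pd.DataFrame:
    """Full two-step triage: returns one row per feature with columns
    feature_id, route ∈ {statistical, heuristic_candidate, dropped},
    n_subgroups_detected and triggers. The three routes partition the
    feature set."""
    freq = detection_frequency(matrix, samples)
    elig = statistical_eligibility(freq, min_freq=min_freq, min_subgroups=min_subgroups)
    pool = elig.loc[elig["route"] == "heuristic_pool", "feature_id"].tolist()
    heur = heuristic_candidates(
        freq, matrix, samples, pool,
        low=low, high=high, fc_up=fc_up, fc_down=fc_down, mode=mode)
    merged = elig.merge(heur, on="feature_id", how="left", suffixes=("", "_heur"))
    is_pool = merged["route"] == "heuristic_pool"
    merged.loc[is_pool, "route"] = merged.loc[is_pool, "route_heur"]
    merged["triggers"] = merged["triggers"].fillna("")
    return merged[["feature_id", "route", "n_subgroups_detected", "triggers"]]
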