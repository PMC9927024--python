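"""Seeded synthetic crossover cohorts with known ground truth.

The generator emulates the data structure of a randomized two-trial
crossover urine study: ``n_subjects`` subjects each perform a moderate
(CME) and a vigorous (CVE) endurance-exercise trial in randomized order,
with urine sampled at five time points per trial. Metabolite abundances
follow a log-normal model with a subject random effect:

    log value(f, s, t, u) = mu_f + b_{f,s} + beta * log(osmo_s / osmo_ref)
                            + log fc_f(t, u) + eps

with b ~ N(0, sd_subject²), eps ~ N(0, sd_resid²). Effects are
multiplicative templates over time points (transient or persistent,
up or down); on the vigorous trial the log fold change is multiplied by
``intensity_scaling``, so a single knob controls the between-trial
contrast. Targeted concentrations carry a dilution term (beta = 1 by
default): urine osmolality falls from U00 to U03 as subjects rehydrate,
and solute concentrations fall proportionally, which is exactly what
osmolality normalization removes. The extra hydration on the vigorous
trial at U03 is modeled as more water in → proportionally larger volume
and lower osmolality, leaving solute excretion unchanged. Untargeted
intensities carry no dilution term (samples are dilution-equalized
upstream of GC×GC-MS) but receive value-dependent left-censoring
(detection probability is a logistic function of log intensity around a
per-feature limit of detection) and multiplicative run-order drift, with
interleaved pooled-QC injections that carry the drift signature.

Ground-truth relevance labels are computed from the noise-free fold
changes with the same strict relevance boundaries the classifier uses,
so parameter-recovery tests compare pipeline calls against an exactly
known target.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classify import LABELS, RelevanceThresholds, fc_relevant
from .io_tables import (
    COLLECTION_PHASES,
    TIMEPOINTS,
    TRIALS,
    MeasurementMatrix,
    SampleRecord,
    ValidationError,
    samples_frame,
    validate_samples,
)

__all__ = [
    "EffectTemplate",
    "DEFAULT_TEMPLATES",
    "SimConfig",
    "TruthTable",
    "Cohort",
    "generate_cohort",
    "simulate_hydration",
    "apply_detection_and_drift",
    "expected_detection_rate",
]


@dataclass(frozen=True)
class EffectTemplate:
    """Multiplicative effect profile over time points.

    ``fc_at`` maps a timepoint to the fold change relative to baseline on
    the moderate trial; omitted time points (always including U00) have
    fold change 1. On the vigorous trial the log fold change is multiplied
    by the cohort's ``intensity_scaling``.
    """

    template_id: str
    fc_at: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for tp, fc in self.fc_at.items():
            if tp not in TIMEPOINTS:
                raise ValidationError(f"template {self.template_id}: bad timepoint {tp}")
            if tp == "U00" and fc != 1.0:
                raise ValidationError(
                    f"template {self.template_id}: baseline fold change must be 1")
            if not fc > 0:
                raise ValidationError(
                    f"template {self.template_id}: fold changes must be > 0")

    def log_fc(self, trial: str, timepoint: str, intensity_scaling: float) -> float:
        lf = math.log(self.fc_at.get(timepoint, 1.0))
        if trial == "CVE":
            lf *= intensity_scaling
        return lf


DEFAULT_TEMPLATES: dict[str, EffectTemplate] = {
    "immediate_transient_up": EffectTemplate(
        "immediate_transient_up", {"U01": 3.0}),
    "persistent_up": EffectTemplate(
        "persistent_up", {"U01": 3.0, "U02": 2.5, "U03": 2.2}),
    "late_down": EffectTemplate(
        "late_down", {"U02": 0.45, "U03": 1.0 / 3.0}),
    "persistent_down": EffectTemplate(
        "persistent_down", {"U01": 1.0 / 3.0, "U02": 1.0 / 3.0, "U03": 1.0 / 3.0}),
    "null": EffectTemplate("null", {}),
}


def _default_fractions() -> dict[str, float]:
    return {
        "null": 0.70,
        "immediate_transient_up": 0.075,
        "persistent_up": 0.075,
        "late_down": 0.075,
        "persistent_down": 0.075,
    }


@dataclass
class SimConfig:
    """Synthetic-cohort parameters; defaults emulate the study design
    (16 subjects, 44 targeted metabolites on two platforms with 8 shared,
    608 untargeted spectral features)."""

    n_subjects: int = 16
    n_targeted: int = 44
    n_lcms: int = 19
    n_shared: int = 8
    n_untargeted: int = 608
    template_fractions: dict[str, float] = field(default_factory=_default_fractions)
    templates: dict[str, EffectTemplate] = field(
        default_factory=lambda: dict(DEFAULT_TEMPLATES))
    intensity_scaling: float = 2.0
    # log-scale (natural log) variance components
    sd_subject: float = 0.4
    sd_resid: float = 0.3
    platform_noise_sd: float = 0.05
    targeted_mu_log_mean: float = math.log(50.0)   # µmol/L
    targeted_mu_log_sd: float = 1.0
    untargeted_mu_log_mean: float = math.log(1.0e4)  # arbitrary intensity units
    untargeted_mu_log_sd: float = 1.2
    dilution_coupling: float = 1.0
    # hydration time course (mOsm/kg; liters)
    osmolality_mean: dict[str, float] = field(default_factory=lambda: {
        "U00": 700.0, "U01": 500.0, "U02": 350.0, "U03": 250.0, "U04": 650.0})
    osmolality_sd_log: float = 0.15
    osmolality_reference: float = 700.0
    cve_u03_hydration_factor: float = 0.8
    volume_mean: dict[str, float] = field(default_factory=lambda: {
        "U01": 0.35, "U02": 0.45, "U03": 0.55})
    volume_sd_log: float = 0.25
    # detection (left-censoring) model for untargeted features
    detection_enabled: bool = True
    lod_offset_mean: float = 3.0   # log units below the feature mean
    lod_offset_sd: float = 1.0
    detection_slope: float = 1.2   # logistic steepness per log unit
    # run-order drift model and QC interleaving
    qc_interval: int = 16
    min_qc_per_run: int = 5
    drift_linear_sd: float = 0.08
    drift_smooth_sd: float = 0.04
    drift_period_frac: float = 0.5
    qc_noise_sd: float = 0.03
    seed: int = 0

    def validate(self) -> None:
        if self.n_subjects < 3:
            raise ValidationError("n_subjects must be >= 3 (paired tests degenerate)")
        if abs(sum(self.template_fractions.values()) - 1.0) > 1e-9:
            raise ValidationError("template fractions must sum to 1")
        unknown = set(self.template_fractions) - set(self.templates)
        if unknown:
            raise ValidationError(f"fractions reference unknown templates {unknown}")
        for name in ("sd_subject", "sd_resid", "platform_noise_sd",
                     "osmolality_sd_log", "volume_sd_log", "qc_noise_sd",
                     "drift_linear_sd", "drift_smooth_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if not (0 < self.n_lcms <= self.n_targeted
                and 0 <= self.n_shared <= self.n_lcms):
            raise ValidationError("inconsistent targeted platform counts")
        for tp, mean in {**self.osmolality_mean, **self.volume_mean}.items():
            if not mean > 0:
                raise ValidationError(f"nonpositive configured mean for {tp}")
        if not self.intensity_scaling >= 1:
            raise ValidationError("intensity_scaling must be >= 1")

    def noise_free(self) -> "SimConfig":
        """A copy with all noise sources off, missingness and drift
        disabled: the pipeline then recovers the truth labels exactly."""
        return replace(
            self, sd_subject=0.0, sd_resid=0.0, platform_noise_sd=0.0,
            osmolality_sd_log=0.0, volume_sd_log=0.0, qc_noise_sd=0.0,
            drift_linear_sd=0.0, drift_smooth_sd=0.0, detection_enabled=False)


@dataclass
class TruthTable:
    """Ground-truth effect profile per feature.

    ``labels`` has one row per feature (template, platform_class and the
    three relevance labels); ``fcs`` holds the noise-free fold change per
    main comparison. Labels are derived from ``fcs`` by thresholding with
    the classifier's strict relevance boundaries.
    """

    labels: pd.DataFrame
    fcs: pd.DataFrame


@dataclass
class Cohort:
    """One generated crossover dataset (tables plus ground truth)."""

    samples: list[SampleRecord]
    nmr: MeasurementMatrix
    lcms: MeasurementMatrix
    untargeted: MeasurementMatrix
    feature_meta: pd.DataFrame
    truth: TruthTable
    duplicate_ids: list[str]
    feature_params: pd.DataFrame  # feature_id, mu_log, lod_log, template, platform_class
    drift_curves: pd.DataFrame | None
    config: SimConfig


# ---------------------------------------------------------------------------

def _design_frame(config: SimConfig, rng: np.random.Generator) -> pd.DataFrame:
    """Design coordinates (no physical covariates yet); trial order is
    randomized per subject."""
    rows = []
    for i in range(config.n_subjects):
        subject = f"S{i + 1:02d}"
        cme_first = bool(rng.integers(0, 2))
        order = ("CME", "CVE") if cme_first else ("CVE", "CME")
        for visit, trial in zip(("V1", "V2"), order):
            for tp in TIMEPOINTS:
                rows.append({
                    "sample_id": f"{subject}_{trial}_{tp}",
                    "subject_id": subject, "visit": visit,
                    "trial": trial, "timepoint": tp,
                })
    return pd.DataFrame(rows)


def _trial_hydration(config: SimConfig, trial: str, tp: str) -> tuple[float, float | None]:
    """(osmolality mean, volume mean) for one design cell; the vigorous
    trial's extra water intake at U03 lowers osmolality and raises volume
    by the same factor, preserving solute excretion."""
    osmo = config.osmolality_mean[tp]
    vol = config.volume_mean.get(tp)
    if trial == "CVE" and tp == "U03":
        h = config.cve_u03_hydration_factor
        osmo *= h
        if vol is not None:
            vol /= h
    return osmo, vol


def simulate_hydration(
    config: SimConfig,
    design: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> list[SampleRecord]:
    """Fill osmolality (all time points) and urine volumes (collection
    phases U01–U03) onto design coordinates, returning validated sample
    records. Osmolality declines from U00 to U03 with a lower U03 mean on
    the vigorous trial; with zero configured variances the draws equal the
    mean profiles exactly."""
    config.validate()
    rng = rng if rng is not None else np.random.default_rng([config.seed, 1])
    records = []
    for row in design.itertuples(index=False):
        osmo_mean, vol_mean = _trial_hydration(config, row.trial, row.timepoint)
        osmo = osmo_mean * math.exp(config.osmolality_sd_log * rng.standard_normal())
        vol = None
        if vol_mean is not None:
            vol = vol_mean * math.exp(config.volume_sd_log * rng.standard_normal())
        records.append(SampleRecord(
            sample_id=row.sample_id, subject_id=row.subject_id, visit=row.visit,
            trial=row.trial, timepoint=row.timepoint, urine_volume=vol,
            osmolality=osmo))
    validate_samples(records)
    return records


def _assign_templates(
    config: SimConfig, n_features: int, rng: np.random.Generator
) -> np.ndarray:
    """Largest-remainder allocation of template counts, randomly permuted."""
    names = sorted(config.template_fractions)
    fracs = np.array([config.template_fractions[n] for n in names])
    counts = np.floor(fracs * n_features).astype(int)
    remainder = fracs * n_features - counts
    for i in np.argsort(-remainder)[: n_features - counts.sum()]:
        counts[i] += 1
    assignment = np.repeat(names, counts)
    return assignment[rng.permutation(n_features)]


def _log_values(
    config: SimConfig,
    mu: np.ndarray,
    templates: Sequence[str],
    records: Sequence[SampleRecord],
    rng: np.random.Generator,
    dilution: bool,
) -> np.ndarray:
    """Log-scale value matrix (features × study samples) under the
    log-normal random-effects model."""
    subjects = sorted({r.subject_id for r in records if not r.is_qc})
    subj_index = {s: i for i, s in enumerate(subjects)}
    n_f, n_s = len(mu), len(records)
    b = rng.standard_normal((n_f, len(subjects))) * config.sd_subject
    eps = rng.standard_normal((n_f, n_s)) * config.sd_resid
    log_vals = np.empty((n_f, n_s))
    for j, rec in enumerate(records):
        log_fc = np.array([
            config.templates[t].log_fc(rec.trial, rec.timepoint,
                                       config.intensity_scaling)
            for t in templates])
        col = mu + b[:, subj_index[rec.subject_id]] + log_fc + eps[:, j]
        if dilution and config.dilution_coupling != 0.0:
            col = col + config.dilution_coupling * math.log(
                rec.osmolality / config.osmolality_reference)
        log_vals[:, j] = col
    return log_vals


def apply_detection_and_drift(
    matrix: MeasurementMatrix,
    samples: Sequence[SampleRecord],
    config: SimConfig,
    rng: np.random.Generator | None = None,
    lod_log: np.ndarray | None = None,
    qc_reference: np.ndarray | None = None,
) -> tuple[MeasurementMatrix, list[SampleRecord], pd.DataFrame]:
    """Apply value-dependent left-censoring and multiplicative run-order
    drift to an untargeted matrix, appending interleaved QC injections.

    Injection order is a seeded permutation of the study samples with one
    QC before every ``qc_interval`` study injections plus one at the end
    (at least ``min_qc_per_run``). Each cell is set missing with
    probability 1 − logistic(slope · (log v − LOD_f)); surviving values
    are multiplied by the feature's drift curve at its injection order.
    QC values are the feature's reference level × drift × noise. Returns
    (matrix with QC columns, updated sample records, true drift curves).
    """
    config.validate()
    if matrix.basis != "raw":
        raise ValidationError("detection/drift apply to the raw basis")
    rng = rng if rng is not None else np.random.default_rng([config.seed, 3])
    features = matrix.values.index
    n_f = len(features)
    study = [r for r in samples if not r.is_qc]
    study_ids = [r.sample_id for r in study]
    if set(study_ids) - set(matrix.values.columns):
        raise ValidationError("matrix lacks columns for some study samples")

    # --- injection sequence: QC, k study samples, QC, ... , final QC
    perm = rng.permutation(len(study_ids))
    seq: list[tuple[str, str]] = []
    qc_count = 0
    for pos, idx in enumerate(perm):
        if pos % config.qc_interval == 0:
            qc_count += 1
            seq.append(("qc", f"QC{qc_count:02d}"))
        seq.append(("study", study_ids[idx]))
    qc_count += 1
    seq.append(("qc", f"QC{qc_count:02d}"))
    while qc_count < config.min_qc_per_run:
        qc_count += 1
        seq.append(("qc", f"QC{qc_count:02d}"))
    n_inj = len(seq)
    order_of = {sid: k + 1 for k, (_, sid) in enumerate(seq)}

    # --- per-feature drift curves over injection order
    orders = np.arange(1, n_inj + 1, dtype=float)
    lin = rng.standard_normal(n_f) * config.drift_linear_sd
    smooth_amp = rng.standard_normal(n_f) * config.drift_smooth_sd
    phase = rng.uniform(0, 2 * np.pi, n_f)
    period = max(2.0, config.drift_period_frac * n_inj)
    centered = 2.0 * (orders - (n_inj + 1) / 2.0) / n_inj
    drift = (1.0
             + lin[:, None] * centered[None, :]
             + smooth_amp[:, None] * np.sin(2 * np.pi * orders[None, :] / period
                                            + phase[:, None]))
    drift = np.clip(drift, 0.2, None)
    drift_df = pd.DataFrame(drift, index=features, columns=orders.astype(int))

    # --- detection then drift on study samples
    vals = matrix.values[study_ids].to_numpy(dtype=float).copy()
    if config.detection_enabled:
        if lod_log is None:
            raise ValidationError("detection enabled but no per-feature LOD given")
        with np.errstate(divide="ignore"):
            logv = np.log(vals)
        p_detect = 1.0 / (1.0 + np.exp(-config.detection_slope
                                       * (logv - lod_log[:, None])))
        vals[rng.random(vals.shape) >= p_detect] = np.nan
    study_orders = np.array([order_of[s] for s in study_ids])
    vals *= drift[:, study_orders - 1]

    # --- QC columns
    if qc_reference is None:
        qc_reference = np.nanmedian(matrix.values.to_numpy(dtype=float), axis=1)
    qc_ids = [sid for kind, sid in seq if kind == "qc"]
    qc_orders = np.array([order_of[s] for s in qc_ids])
    qc_noise = np.exp(rng.standard_normal((n_f, len(qc_ids))) * config.qc_noise_sd)
    qc_vals = qc_reference[:, None] * drift[:, qc_orders - 1] * qc_noise

    out_vals = pd.DataFrame(
        np.concatenate([vals, qc_vals], axis=1),
        index=features, columns=study_ids + qc_ids)
    out_matrix = MeasurementMatrix(platform=matrix.platform, basis="raw",
                                   values=out_vals)
    new_records = [replace(r, injection_order=order_of.get(r.sample_id))
                   for r in samples]
    new_records += [SampleRecord(sample_id=sid, injection_order=order_of[sid],
                                 is_qc=True) for sid in qc_ids]
    validate_samples(new_records)
    return out_matrix, new_records, drift_df


# ---------------------------------------------------------------------------
# ground truth

def _noise_free_fc_table(
    config: SimConfig, features: Sequence[str], templates: Sequence[str],
    targeted: bool,
) -> pd.DataFrame:
    """Noise-free fold change per feature for every main comparison."""
    cols: dict[str, list[float]] = {}
    for trial in TRIALS:
        for tp in COLLECTION_PHASES:
            cols[f"within_{trial}_U00_{tp}"] = [
                math.exp(config.templates[t].log_fc(trial, tp,
                                                    config.intensity_scaling))
                for t in templates]
    for tp in COLLECTION_PHASES:
        cols[f"between_{tp}"] = [
            math.exp(config.templates[t].log_fc("CVE", tp, config.intensity_scaling)
                     - config.templates[t].log_fc("CME", tp, config.intensity_scaling))
            for t in templates]
    if targeted:
        # solute excretion: conc ∝ osmolality (dilution), amount = conc × vol;
        # the trial hydration factor cancels in the osmo × vol product.
        def weight(trial, tp):
            osmo, vol = _trial_hydration(config, trial, tp)
            return (osmo / config.osmolality_reference) ** config.dilution_coupling * vol

        for tp in COLLECTION_PHASES:
            cols[f"between_{tp}_excretion"] = [
                weight("CVE", tp) / weight("CME", tp)
                * math.exp(config.templates[t].log_fc("CVE", tp, config.intensity_scaling)
                           - config.templates[t].log_fc("CME", tp, config.intensity_scaling))
                for t in templates]
        cols["between_cumulative_excretion"] = [
            sum(weight("CVE", tp)
                * math.exp(config.templates[t].log_fc("CVE", tp, config.intensity_scaling))
                for tp in COLLECTION_PHASES)
            / sum(weight("CME", tp)
                  * math.exp(config.templates[t].log_fc("CME", tp, config.intensity_scaling))
                  for tp in COLLECTION_PHASES)
            for t in templates]
    return pd.DataFrame(cols, index=pd.Index(features, name="feature_id"))


def _truth_from_fcs(
    fcs: pd.DataFrame, templates: Sequence[str], platform_class: str,
    thresholds: RelevanceThresholds,
) -> pd.DataFrame:
    th = thresholds.for_class(platform_class)
    rows = []
    for (feature, fc_row), template in zip(fcs.iterrows(), templates):
        labels = {name: False for name in LABELS}
        for cid, fc in fc_row.items():
            if not fc_relevant(fc, th):
                continue
            if cid.startswith("within_CME"):
                labels["exercise_responsive_CME"] = True
            elif cid.startswith("within_CVE"):
                labels["exercise_responsive_CVE"] = True
            elif cid.startswith("between"):
                labels["intensity_dependent"] = True
        rows.append({"feature_id": feature, "template": template,
                     "platform_class": platform_class, **labels})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------

_PATHWAYS = ("Amino acids", "Organic acids", "TCA cycle", "Glycolysis",
             "Purine metabolism", "Osmolytes", "Xenobiotics")


def generate_cohort(
    config: SimConfig | None = None,
    thresholds: RelevanceThresholds | None = None,
) -> Cohort:
    """Generate one seeded synthetic crossover dataset.

    Deterministic for a fixed config (including its seed): repeated calls
    return bit-identical tables. The returned :class:`Cohort` bundles the
    sample records (with QC injections and run order), the two targeted
    matrices (sharing ``n_shared`` duplicate metabolites), the untargeted
    matrix with missingness and drift, feature metadata, per-feature
    simulation parameters, the true drift curves, and the ground-truth
    relevance labels.
    """
    config = config or SimConfig()
    config.validate()
    thresholds = thresholds or RelevanceThresholds()

    design = _design_frame(config, np.random.default_rng([config.seed, 0]))
    records = simulate_hydration(config, design,
                                 np.random.default_rng([config.seed, 1]))

    rng_v = np.random.default_rng([config.seed, 2])
    # --- targeted features: distinct metabolites, LC-MS block first
    t_ids = [f"met_{i + 1:02d}" for i in range(config.n_targeted)]
    lcms_ids = t_ids[: config.n_lcms]
    nmr_only_ids = t_ids[config.n_lcms:]
    duplicate_ids = lcms_ids[: config.n_shared]
    nmr_ids = nmr_only_ids + duplicate_ids
    t_templates = _assign_templates(config, config.n_targeted, rng_v)
    t_mu = (config.targeted_mu_log_mean
            + rng_v.standard_normal(config.n_targeted) * config.targeted_mu_log_sd)
    t_log = _log_values(config, t_mu, t_templates, records, rng_v, dilution=True)
    t_vals = pd.DataFrame(np.exp(t_log), index=t_ids,
                          columns=[r.sample_id for r in records])
    lcms = MeasurementMatrix("LC-MS", "raw", t_vals.loc[lcms_ids].copy())
    nmr_vals = t_vals.loc[nmr_ids].copy()
    if config.platform_noise_sd > 0:
        nmr_vals *= np.exp(rng_v.standard_normal(nmr_vals.shape)
                           * config.platform_noise_sd)
    nmr = MeasurementMatrix("NMR", "raw", nmr_vals)

    # --- untargeted features
    u_ids = [f"ft_{i + 1:04d}" for i in range(config.n_untargeted)]
    u_templates = _assign_templates(config, config.n_untargeted, rng_v)
    u_mu = (config.untargeted_mu_log_mean
            + rng_v.standard_normal(config.n_untargeted) * config.untargeted_mu_log_sd)
    u_lod = u_mu - (config.lod_offset_mean
                    + rng_v.standard_normal(config.n_untargeted) * config.lod_offset_sd)
    u_log = _log_values(config, u_mu, u_templates, records, rng_v, dilution=False)
    u_clean = MeasurementMatrix(
        "GCxGC-MS", "raw",
        pd.DataFrame(np.exp(u_log), index=u_ids,
                     columns=[r.sample_id for r in records]))
    untargeted, records, drift_curves = apply_detection_and_drift(
        u_clean, records, config, np.random.default_rng([config.seed, 3]),
        lod_log=u_lod, qc_reference=np.exp(u_mu))

    # --- metadata
    meta_rows = []
    for i, fid in enumerate(t_ids):
        meta_rows.append({
            "feature_id": fid, "display_name": f"metabolite {i + 1:02d}",
            "platform": "LC-MS" if fid in lcms_ids else "NMR",
            "msi_level": 1, "major_pathway": _PATHWAYS[i % len(_PATHWAYS)],
            "sub_pathway": "", "targeted": True})
    for i, fid in enumerate(u_ids):
        known = i % 3 == 0
        meta_rows.append({
            "feature_id": fid,
            "display_name": f"feature {i + 1:04d}" if not known else f"compound {i + 1:04d}",
            "platform": "GCxGC-MS",
            "msi_level": 2 if known else 4,
            "major_pathway": _PATHWAYS[i % len(_PATHWAYS)] if known else "unclassified",
            "sub_pathway": "", "targeted": False})
    feature_meta = pd.DataFrame(meta_rows)

    # --- ground truth
    t_fcs = _noise_free_fc_table(config, t_ids, t_templates, targeted=True)
    u_fcs = _noise_free_fc_table(config, u_ids, u_templates, targeted=False)
    labels = pd.concat([
        _truth_from_fcs(t_fcs, t_templates, "targeted", thresholds),
        _truth_from_fcs(u_fcs, u_templates, "untargeted", thresholds),
    ], ignore_index=True)
    truth = TruthTable(labels=labels, fcs=pd.concat([t_fcs, u_fcs]))

    feature_params = pd.DataFrame({
        "feature_id": t_ids + u_ids,
        "mu_log": np.concatenate([t_mu, u_mu]),
        "lod_log": np.concatenate([np.full(config.n_targeted, -np.inf), u_lod]),
        "template": np.concatenate([t_templates, u_templates]),
        "platform_class": ["targeted"] * config.n_targeted
                          + ["untargeted"] * config.n_untargeted,
    })
    return Cohort(samples=records, nmr=nmr, lcms=lcms, untargeted=untargeted,
                  feature_meta=feature_meta, truth=truth,
                  duplicate_ids=duplicate_ids, feature_params=feature_params,
                  drift_curves=drift_curves, config=config)


def expected_detection_rate(config: SimConfig, cohort: Cohort, n_nodes: int = 40) -> float:
    """Analytic expected detection probability averaged over all
    (untargeted feature, study sample) cells, by Gauss-Hermite integration
    of the logistic detection model over the log-normal value
    distribution. Compares against the realized non-missing fraction."""
    nodes, weights = np.polynomial.hermite_e.hermegauss(n_nodes)
    weights = weights / weights.sum()
    s = math.hypot(config.sd_subject, config.sd_resid)
    params = cohort.feature_params[
        cohort.feature_params["platform_class"] == "untargeted"]
    study = [r for r in cohort.samples if not r.is_qc]
    total = 0.0
    n_cells = 0
    cell_fcs: dict[tuple[str, str], np.ndarray] = {}
    for trial in TRIALS:
        for tp in TIMEPOINTS:
            cell_fcs[(trial, tp)] = np.array([
                config.templates[t].log_fc(trial, tp, config.intensity_scaling)
                for t in params["template"]])
    mu = params["mu_log"].to_numpy()
    lod = params["lod_log"].to_numpy()
    for rec in study:
        m = mu + cell_fcs[(rec.trial, rec.timepoint)]
        # E[logistic(slope (X - lod))], X ~ N(m, s²)
        x = m[:, None] + s * nodes[None, :]
        p = 1.0 / (1.0 + np.exp(-config.detection_slope * (x - lod[:, None])))
        total += float((p @ weights).sum())
        n_cells += m.size
    return total / n_cells
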