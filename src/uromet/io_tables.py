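"""Tabular I/O and the study-design data model.

The study design is a randomized crossover: each subject performs two
endurance-exercise trials (CME = continuous moderate, CVE = continuous
vigorous) on separate visits (V1/V2), and urine is sampled at five time
points per trial: a fasting pre-exercise spot sample (U00), three timed
post-exercise collection phases (U01, U02, U03 — the only time points with
a measured urine volume), and a next-morning fasting spot sample (U04).
Pooled-urine QC injections interleaved in the instrument run order carry
``is_qc=True`` and no design coordinates.

All tables are UTF-8 CSV/TSV with a header row; missing values are empty
cells; decimal separator is ".".
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

TIMEPOINTS = ("U00", "U01", "U02", "U03", "U04")
COLLECTION_PHASES = ("U01", "U02", "U03")
TRIALS = ("CME", "CVE")
VISITS = ("V1", "V2")
PLATFORMS = ("NMR", "LC-MS", "GCxGC-MS", "targeted")
BASES = (
    "raw",
    "osmolality_normalized",
    "absolute_excretion",
    "cumulative_excretion",
    "drift_corrected",
)
#: basis transitions permitted by the preprocessing DAG
BASIS_TRANSITIONS = {
    "raw": {"osmolality_normalized", "absolute_excretion", "drift_corrected"},
    "absolute_excretion": {"cumulative_excretion"},
}

SAMPLE_COLUMNS = (
    "sample_id",
    "subject_id",
    "visit",
    "trial",
    "timepoint",
    "urine_volume",
    "osmolality",
    "injection_order",
    "is_qc",
)

FLOAT_FORMAT = "%.9g"


class ValidationError(ValueError):
    """A table or record violates the study-design data model."""


@dataclass(frozen=True)
class SampleRecord:
    """One urine sample with design coordinates and physical covariates.

    ``urine_volume`` is in liters and may be present only for the timed
    collection phases U01–U03; ``osmolality`` is in mOsm/kg and is required
    for every non-QC sample. QC injections have no design coordinates.
    """

    sample_id: str
    subject_id: str | None = None
    visit: str | None = None
    trial: str | None = None
    timepoint: str | None = None
    urine_volume: float | None = None
    osmolality: float | None = None
    injection_order: int | None = None
    is_qc: bool = False

    def __post_init__(self) -> None:
        if self.is_qc:
            if self.subject_id or self.trial or self.timepoint:
                raise ValidationError(
                    f"QC sample {self.sample_id!r} must not carry design coordinates"
                )
        else:
            if self.timepoint not in TIMEPOINTS:
                raise ValidationError(
                    f"sample {self.sample_id!r}: unknown timepoint {self.timepoint!r}"
                )
            if self.trial not in TRIALS:
                raise ValidationError(
                    f"sample {self.sample_id!r}: unknown trial {self.trial!r}"
                )
            if self.visit is not None and self.visit not in VISITS:
                raise ValidationError(
                    f"sample {self.sample_id!r}: unknown visit {self.visit!r}"
                )
            if self.subject_id in (None, ""):
                raise ValidationError(f"sample {self.sample_id!r}: missing subject_id")
            if self.osmolality is None:
                raise ValidationError(
                    f"sample {self.sample_id!r}: missing osmolality on a non-QC sample"
                )
        if self.osmolality is not None and not self.osmolality > 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: osmolality must be > 0, got {self.osmolality}"
            )
        if self.urine_volume is not None:
            if self.is_qc or self.timepoint not in COLLECTION_PHASES:
                raise ValidationError(
                    f"sample {self.sample_id!r}: urine volume is only defined for "
                    f"collection phases {COLLECTION_PHASES}, found one on "
                    f"timepoint {self.timepoint!r}"
                )
            if not self.urine_volume > 0:
                raise ValidationError(
                    f"sample {self.sample_id!r}: urine volume must be > 0, "
                    f"got {self.urine_volume}"
                )
        if self.injection_order is not None and not self.injection_order > 0:
            raise ValidationError(
                f"sample {self.sample_id!r}: injection order must be a positive "
                f"integer, got {self.injection_order}"
            )


def validate_samples(records: Sequence[SampleRecord]) -> None:
    """Check cross-record invariants of a sample table.

    Raises :class:`ValidationError` on duplicate sample ids, duplicate
    (subject, trial, timepoint) design cells, more than two trials per
    subject, or an inconsistent visit-to-trial assignment within a subject.
    """
    seen_ids: set[str] = set()
    design: set[tuple] = set()
    subject_trials: dict[str, dict[str, str | None]] = {}
    for rec in records:
        if rec.sample_id in seen_ids:
            raise ValidationError(f"duplicate sample_id {rec.sample_id!r}")
        seen_ids.add(rec.sample_id)
        if rec.is_qc:
            continue
        key = (rec.subject_id, rec.trial, rec.timepoint)
        if key in design:
            raise ValidationError(
                f"duplicate (subject, trial, timepoint) record: {key}"
            )
        design.add(key)
        trials = subject_trials.setdefault(rec.subject_id, {})
        if rec.trial in trials:
            if trials[rec.trial] != rec.visit:
                raise ValidationError(
                    f"subject {rec.subject_id!r}: trial {rec.trial} assigned to "
                    f"both visits {trials[rec.trial]} and {rec.visit}"
                )
        else:
            trials[rec.trial] = rec.visit
        if len(trials) > 2:
            raise ValidationError(
                f"subject {rec.subject_id!r} has more than 2 trials: {sorted(trials)}"
            )
    for subject, trials in subject_trials.items():
        visits = [v for v in trials.values() if v is not None]
        if len(visits) == 2 and visits[0] == visits[1]:
            raise ValidationError(
                f"subject {subject!r}: both trials assigned to visit {visits[0]}"
            )


def samples_frame(records: Sequence[SampleRecord]) -> pd.DataFrame:
    """Long-format view of sample records, indexed by sample_id."""
    df = pd.DataFrame([rec.__dict__ for rec in records], columns=SAMPLE_COLUMNS)
    return df.set_index("sample_id", drop=False)


def _sep_for(path: str) -> str:
    return "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","


def read_sample_table(path: str | os.PathLike) -> list[SampleRecord]:
    """Read and validate a sample metadata table (CSV/TSV)."""
    df = pd.read_csv(path, sep=_sep_for(path), dtype={"sample_id": str, "subject_id": str})
    missing = set(SAMPLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValidationError(f"sample table {path}: missing columns {sorted(missing)}")
    records = []
    for row in df.itertuples(index=False):
        is_qc = _parse_bool(row.is_qc)
        records.append(
            SampleRecord(
                sample_id=str(row.sample_id),
                subject_id=_opt_str(row.subject_id) if not is_qc else None,
                visit=_opt_str(row.visit) if not is_qc else None,
                trial=_opt_str(row.trial) if not is_qc else None,
                timepoint=_opt_str(row.timepoint) if not is_qc else None,
                urine_volume=_opt_float(row.urine_volume),
                osmolality=_opt_float(row.osmolality),
                injection_order=_opt_int(row.injection_order),
                is_qc=is_qc,
            )
        )
    validate_samples(records)
    return records


def write_sample_table(records: Sequence[SampleRecord], path: str | os.PathLike) -> None:
    df = samples_frame(records)
    df.to_csv(path, sep=_sep_for(path), index=False, float_format=FLOAT_FORMAT)


def _parse_bool(x) -> bool:
    if isinstance(x, (bool, np.bool_)):
        return bool(x)
    if isinstance(x, (int, np.integer, float)):
        return bool(int(x))
    return str(x).strip().lower() in ("true", "1", "yes")


def _opt_str(x) -> str | None:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return None
    s = str(x).strip()
    return s or None


def _opt_float(x) -> float | None:
    if x is None or x == "":
        return None
    v = float(x)
    return None if np.isnan(v) else v


def _opt_int(x) -> int | None:
    v = _opt_float(x)
    return None if v is None else int(v)


@dataclass
class MeasurementMatrix:
    """Feature × sample value matrix with a platform tag and a value basis.

    ``values`` is a DataFrame indexed by feature_id with sample_id columns;
    missing cells (NaN) are permitted only for the untargeted GCxGC-MS
    platform. All values are non-negative. ``basis`` records where the
    matrix sits in the preprocessing DAG (raw -> osmolality_normalized /
    absolute_excretion / drift_corrected).
    """

    platform: str
    basis: str
    values: pd.DataFrame

    def __post_init__(self) -> None:
        if self.platform not in PLATFORMS:
            raise ValidationError(f"unknown platform {self.platform!r}")
        if self.basis not in BASES:
            raise ValidationError(f"unknown basis {self.basis!r}")
        vals = self.values.to_numpy(dtype=float)
        if np.isnan(vals).any() and self.platform != "GCxGC-MS":
            raise ValidationError(
                f"missing values are not permitted for platform {self.platform}"
            )
        if np.nanmin(vals, initial=0.0) < 0:
            raise ValidationError("measurement values must be >= 0 or missing")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValidationError(f"duplicate feature ids: {dups[:5]}")
        self.values.index.name = "feature_id"
        self.values.columns.name = None

    @property
    def features(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def with_values(self, values: pd.DataFrame, basis: str) -> "MeasurementMatrix":
        """Derive a matrix on a new basis, enforcing the preprocessing DAG."""
        if basis != self.basis and basis not in BASIS_TRANSITIONS.get(self.basis, ()):
            raise ValidationError(
                f"illegal basis transition {self.basis!r} -> {basis!r}"
            )
        return MeasurementMatrix(platform=self.platform, basis=basis, values=values)

    def check_samples(self, records: Sequence[SampleRecord]) -> None:
        known = {rec.sample_id for rec in records}
        unknown = [s for s in self.values.columns if s not in known]
        if unknown:
            raise ValidationError(
                f"matrix references unknown sample ids: {unknown[:10]}"
            )


def read_measurement_table(path: str | os.PathLike, platform: str) -> MeasurementMatrix:
    """Read a feature table (wide: feature_id + one column per sample, or
    long: feature_id, sample_id, value) as a raw-basis matrix.

    Empty cells become missing; missing cells are rejected for the targeted
    platforms (NMR, LC-MS); negative values are always rejected.
    """
    df = pd.read_csv(path, sep=_sep_for(path))
    cols = set(df.columns)
    if cols == {"feature_id", "sample_id", "value"}:
        wide = df.pivot(index="feature_id", columns="sample_id", values="value")
    else:
        first = df.columns[0]
        wide = df.set_index(first)
        wide.index.name = "feature_id"
    wide = wide.astype(float)
    if (wide.to_numpy() < 0).any():
        bad = wide.index[(wide < 0).any(axis=1)].tolist()
        raise ValidationError(f"negative values for features {bad[:5]}")
    return MeasurementMatrix(platform=platform, basis="raw", values=wide)


def write_measurement_table(matrix: MeasurementMatrix, path: str | os.PathLike) -> None:
    matrix.values.to_csv(path, sep=_sep_for(path), index_label="feature_id",
                         float_format=FLOAT_FORMAT)


FEATURE_META_COLUMNS = (
    "feature_id",
    "display_name",
    "platform",
    "msi_level",
    "major_pathway",
    "sub_pathway",
    "targeted",
)


def validate_feature_meta(meta: pd.DataFrame) -> pd.DataFrame:
    """Validate feature metadata: MSI levels 3/4 must be unclassified."""
    missing = set(FEATURE_META_COLUMNS) - set(meta.columns)
    if missing:
        raise ValidationError(f"feature metadata: missing columns {sorted(missing)}")
    if not meta["msi_level"].isin([1, 2, 3, 4]).all():
        raise ValidationError("msi_level must be in {1,2,3,4}")
    low_conf = meta["msi_level"].isin([3, 4])
    bad = meta.loc[low_conf & (meta["major_pathway"] != "unclassified"), "feature_id"]
    if len(bad):
        raise ValidationError(
            f"MSI level 3/4 features must have major_pathway='unclassified': "
            f"{bad.tolist()[:5]}"
        )
    return meta


def read_feature_meta(path: str | os.PathLike) -> pd.DataFrame:
    meta = pd.read_csv(path, sep=_sep_for(path),
                       dtype={"feature_id": str, "display_name": str},
                       keep_default_na=False,
                       na_values=[])
    meta["msi_level"] = meta["msi_level"].astype(int)
    meta["targeted"] = meta["targeted"].map(_parse_bool)
    return validate_feature_meta(meta)


def write_feature_meta(meta: pd.DataFrame, path: str | os.PathLike) -> None:
    meta.to_csv(path, sep=_sep_for(path), index=False)


def write_results(
    comparisons: pd.DataFrame,
    calls: pd.DataFrame,
    out_dir: str | os.PathLike,
    venn_counts: pd.DataFrame | None = None,
    heatmap: pd.DataFrame | None = None,
) -> dict[str, str]:
    """Write the analysis output tables to ``out_dir``.

    Floats are serialized with 9 significant digits so a write/read
    round-trip reproduces values at that precision. Returns the mapping of
    logical table name to file path.
    """
    if comparisons is None or len(comparisons) == 0:
        raise ValidationError("refusing to write an empty comparisons table")
    if calls is None or len(calls) == 0:
        raise ValidationError("refusing to write an empty relevance-call table")
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    paths = {}
    tables = {"comparisons.tsv": (comparisons, False),
              "relevance_calls.tsv": (calls, False)}
    if venn_counts is not None:
        tables["venn_counts.tsv"] = (venn_counts, False)
    if heatmap is not None:
        tables["heatmap_matrix.tsv"] = (heatmap, True)
    for name, (table, keep_index) in tables.items():
        path = os.path.join(out_dir, name)
        table.to_csv(path, sep="\t", index=keep_index, float_format=FLOAT_FORMAT)
        paths[name] = path
    return paths
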