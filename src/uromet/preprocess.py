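"""Transforms from raw measurements onto the analysis bases.

Targeted (NMR / LC-MS) concentrations are normalized to urine osmolality
to control for dilution, and converted to absolute excretion per timed
collection phase (concentration × collected volume) plus a cumulative
post-exercise excretion (U01 + U02 + U03). Metabolites quantified on both
targeted platforms are merged into one matrix preferring the LC-MS
values, with a between-platform R² agreement report. Untargeted GC×GC-MS
intensities instead receive a QC-anchored signal-drift correction: per
feature, a tricube-weighted local linear (LOWESS, degree 1) trend is
fitted to the interleaved pooled-urine QC injections as a function of
injection order, and every study value is divided by the trend relative
to the feature's median QC level. Untargeted features are NOT osmolality
normalized (samples are dilution-equalized before GC×GC-MS acquisition),
and targeted features are never drift-corrected (calibrated
quantification).
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io_tables import (
    COLLECTION_PHASES,
    MeasurementMatrix,
    SampleRecord,
    ValidationError,
    samples_frame,
)

__all__ = [
    "normalize_osmolality",
    "compute_excretion",
    "merge_platforms",
    "qc_drift_correct",
]

logger = logging.getLogger(__name__)

#: correction factors outside this range are clipped (run-edge blow-up guard)
FACTOR_CLIP = (0.2, 5.0)


def _frame(samples) -> pd.DataFrame:
    return samples if isinstance(samples, pd.DataFrame) else samples_frame(samples)


def normalize_osmolality(
    matrix: MeasurementMatrix, samples: Sequence[SampleRecord] | pd.DataFrame
) -> MeasurementMatrix:
    """Divide each sample's concentrations by its osmolality (mOsm/kg).

    Applies to targeted platforms on the raw basis, at all five time
    points. Scaling a sample's concentrations and its osmolality by the
    same dilution factor leaves the result unchanged.
    """
    if matrix.platform not in ("NMR", "LC-MS", "targeted"):
        raise ValidationError(
            f"osmolality normalization applies to targeted platforms, "
            f"not {matrix.platform}")
    if matrix.basis != "raw":
        raise ValidationError(f"expected raw basis, got {matrix.basis!r}")
    sdf = _frame(samples)
    osmo = []
    for sample_id in matrix.values.columns:
        if sample_id not in sdf.index:
            raise ValidationError(f"unknown sample id {sample_id!r}")
        value = sdf.loc[sample_id, "osmolality"]
        if value is None or not np.isfinite(value) or value <= 0:
            raise ValidationError(
                f"sample {sample_id!r}: osmolality must be > 0 for normalization")
        osmo.append(float(value))
    normalized = matrix.values / np.asarray(osmo)[np.newaxis, :]
    return matrix.with_values(normalized, basis="osmolality_normalized")


def compute_excretion(
    matrix: MeasurementMatrix,
    samples: Sequence[SampleRecord] | pd.DataFrame,
    timepoints: Sequence[str] = COLLECTION_PHASES,
) -> pd.DataFrame:
    """Absolute metabolite excretion per collection phase, in µmol.

    amount = concentration (µmol/L) × collected urine volume (L), defined
    only for the timed phases U01–U03. One cumulative record per
    (feature, subject, trial) sums the three phases when all three are
    present. Returns a long DataFrame with columns feature_id,
    subject_id, trial, phase (U01/U02/U03/cumulative), amount.
    """
    bad = [tp for tp in timepoints if tp not in COLLECTION_PHASES]
    if bad:
        raise ValidationError(
            f"excretion is only defined for collection phases "
            f"{COLLECTION_PHASES}, requested {bad}")
    if matrix.basis != "raw":
        raise ValidationError(f"expected raw basis, got {matrix.basis!r}")
    sdf = _frame(samples)
    sub = sdf[(~sdf["is_qc"]) & sdf["timepoint"].isin(timepoints)
              & sdf["sample_id"].isin(matrix.values.columns)]
    pieces = []
    for row in sub.itertuples(index=False):
        if row.urine_volume is None or not np.isfinite(row.urine_volume):
            raise ValidationError(
                f"sample {row.sample_id!r}: missing urine volume for excretion")
        amounts = matrix.values[row.sample_id] * float(row.urine_volume)
        pieces.append(pd.DataFrame({
            "feature_id": matrix.values.index,
            "subject_id": row.subject_id,
            "trial": row.trial,
            "phase": row.timepoint,
            "amount": amounts.to_numpy(),
        }))
    if not pieces:
        raise ValidationError("no collection-phase samples found for excretion")
    long = pd.concat(pieces, ignore_index=True)
    complete = (
        long.groupby(["feature_id", "subject_id", "trial"])
        .filter(lambda g: set(g["phase"]) == set(COLLECTION_PHASES))
    )
    cumulative = (
        complete.groupby(["feature_id", "subject_id", "trial"], as_index=False)
        ["amount"].sum()
    )
    cumulative["phase"] = "cumulative"
    return pd.concat([long, cumulative[long.columns]], ignore_index=True)


def merge_platforms(
    nmr: MeasurementMatrix,
    lcms: MeasurementMatrix,
    duplicate_map: Sequence[str] | Mapping[str, str],
    r2_floor: float = 0.87,
) -> tuple[MeasurementMatrix, pd.DataFrame]:
    """Merge the two targeted matrices, preferring LC-MS for metabolites
    quantified by both platforms.

    ``duplicate_map`` maps NMR feature ids to LC-MS feature ids (a plain
    sequence means the ids coincide). The agreement report carries the
    between-platform R² per duplicate over shared samples; duplicates with
    R² below ``r2_floor`` are logged as warnings, never errors. The merged
    matrix keeps each duplicate once (the LC-MS values) under platform tag
    "targeted".
    """
    if isinstance(duplicate_map, Mapping):
        dup = dict(duplicate_map)
    else:
        dup = {fid: fid for fid in duplicate_map}
    for nmr_id, lcms_id in dup.items():
        if nmr_id not in nmr.values.index:
            raise ValidationError(f"duplicate {nmr_id!r} absent from NMR matrix")
        if lcms_id not in lcms.values.index:
            raise ValidationError(f"duplicate {lcms_id!r} absent from LC-MS matrix")
    shared = [s for s in nmr.values.columns if s in set(lcms.values.columns)]
    if not shared:
        raise ValidationError("matrices share no samples")
    report_rows = []
    for nmr_id, lcms_id in dup.items():
        x = nmr.values.loc[nmr_id, shared].to_numpy(dtype=float)
        y = lcms.values.loc[lcms_id, shared].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            r2 = np.nan
        else:
            r2 = float(np.corrcoef(x, y)[0, 1] ** 2)
        warn = bool(np.isnan(r2) or r2 < r2_floor)
        if warn:
            logger.warning(
                "platform agreement below floor for %s/%s: R²=%.3f < %.2f",
                nmr_id, lcms_id, r2, r2_floor)
        report_rows.append({"nmr_id": nmr_id, "lcms_id": lcms_id,
                            "r2": r2, "warn": warn})
    keep_nmr = [f for f in nmr.values.index if f not in dup]
    merged_values = pd.concat(
        [lcms.values[shared], nmr.values.loc[keep_nmr, shared]])
    merged = MeasurementMatrix(platform="targeted", basis="raw", values=merged_values)
    return merged, pd.DataFrame(report_rows)


def local_linear_smoother(
    x: np.ndarray, xvals: np.ndarray, span: float
) -> np.ndarray:
    """Smoother matrix S of a tricube-weighted local linear (degree-1,
    non-robust LOWESS) fit: predictions at ``xvals`` are S @ y for
    observations y at ``x``.

    Each evaluation point uses the ``int(span * n)`` nearest observations
    with tricube weights scaled by the bandwidth (distance to the farthest
    neighbor). The fit is exact for data linear in x and reduces to a
    weighted mean when the local design is degenerate, so a constant trace
    maps to a constant prediction. Expressing the fit as a matrix lets one
    smoother serve every feature that shares the QC grid.
    """
    x = np.asarray(x, dtype=float)
    xvals = np.asarray(xvals, dtype=float)
    n = x.size
    if n < 2:
        raise ValidationError("need at least 2 points to fit a drift trend")
    k = min(n, max(2, int(span * n)))
    S = np.zeros((xvals.size, n))
    for j, x0 in enumerate(xvals):
        d = np.abs(x - x0)
        idx = np.argpartition(d, k - 1)[:k]
        h = d[idx].max()
        if h == 0:
            S[j, idx] = 1.0 / idx.size
            continue
        w = (1.0 - np.minimum(d[idx] / h, 1.0) ** 3) ** 3
        sw = w.sum()
        if sw <= 0:
            S[j, idx] = 1.0 / idx.size
            continue
        xs = x[idx]
        xbar = (w * xs).sum() / sw
        sxx = (w * (xs - xbar) ** 2).sum()
        if sxx <= 1e-12 * max(1.0, xbar ** 2):
            S[j, idx] = w / sw
        else:
            S[j, idx] = w * (1.0 / sw + (x0 - xbar) * (xs - xbar) / sxx)
    return S


def qc_drift_correct(
    matrix: MeasurementMatrix,
    samples: Sequence[SampleRecord] | pd.DataFrame,
    span: float = 0.75,
    min_qc: int = 5,
) -> tuple[MeasurementMatrix, pd.DataFrame]:
    """QC-anchored multiplicative signal-drift correction.

    Per feature, a LOWESS (tricube-weighted, degree-1, non-robust) trend
    g(order) is fitted to the non-missing QC intensities versus injection
    order with ``span`` the fraction of QC points per local fit, and
    evaluated at every injection order. Corrected value =
    raw / clip(g(order) / r, 0.2, 5) with r the feature's median QC
    intensity, so a constant QC trace gives the identity correction.
    Features with fewer than ``min_qc`` detected QCs pass through
    uncorrected and are flagged. Missing cells stay missing. Returns the
    drift-corrected matrix and a per-feature report (corrected flag,
    flags).
    """
    if matrix.platform != "GCxGC-MS":
        raise ValidationError("drift correction applies to the untargeted platform")
    if matrix.basis != "raw":
        raise ValidationError(f"expected raw basis, got {matrix.basis!r}")
    sdf = _frame(samples)
    cols = list(matrix.values.columns)
    missing_ids = [c for c in cols if c not in sdf.index]
    if missing_ids:
        raise ValidationError(f"unknown sample ids: {missing_ids[:10]}")
    orders = sdf.loc[cols, "injection_order"].to_numpy(dtype=float)
    if np.isnan(orders).any():
        bad = [c for c, o in zip(cols, orders) if np.isnan(o)]
        raise ValidationError(f"samples lack injection order: {bad[:10]}")
    is_qc = sdf.loc[cols, "is_qc"].to_numpy(dtype=bool)
    if not is_qc.any():
        raise ValidationError("no QC samples present; cannot fit drift model")
    qc_orders_all = orders[is_qc]
    values = matrix.values.to_numpy(dtype=float)
    corrected = values.copy()
    # one smoother matrix serves every feature with a complete QC trace
    full_S: np.ndarray | None = None
    report = []
    for i, feature in enumerate(matrix.values.index):
        qc_vals = values[i, is_qc]
        ok = ~np.isnan(qc_vals)
        flags: list[str] = []
        if ok.sum() < min_qc:
            report.append({"feature_id": feature, "corrected": False,
                           "flags": "uncorrected"})
            continue
        qy = qc_vals[ok]
        if ok.all():
            if full_S is None:
                full_S = local_linear_smoother(qc_orders_all, orders, span)
            g = full_S @ qy
        else:
            g = local_linear_smoother(qc_orders_all[ok], orders, span) @ qy
        r = float(np.median(qy))
        if r <= 0:
            report.append({"feature_id": feature, "corrected": False,
                           "flags": "uncorrected;nonpositive_reference"})
            continue
        factor = g / r
        clipped = np.clip(factor, *FACTOR_CLIP)
        touched = (clipped != factor) & ~np.isnan(values[i])
        if touched.any():
            flags.append("clipped")
        corrected[i] = values[i] / clipped
        report.append({"feature_id": feature, "corrected": True,
                       "flags": ";".join(flags)})
    out = matrix.with_values(
        pd.DataFrame(corrected, index=matrix.values.index, columns=cols),
        basis="drift_corrected")
    return out, pd.DataFrame(report)
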