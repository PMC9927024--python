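"""Preprocessing: normalization/excretion identities, platform merge,
and the QC-anchored drift correction."""

import logging

import numpy as np
import pandas as pd
import pytest
from statsmodels.nonparametric.smoothers_lowess import lowess as sm_lowess

from uromet.io_tables import MeasurementMatrix, SampleRecord, ValidationError
from uromet.preprocess import (
    compute_excretion,
    local_linear_smoother,
    merge_platforms,
    normalize_osmolality,
    qc_drift_correct,
)

from .conftest import make_design_samples


class TestNormalizeOsmolality:
    def test_elementwise_division(self, design_samples):
        sample_id = design_samples[0].sample_id
        matrix = MeasurementMatrix("NMR", "raw", pd.DataFrame(
            {sample_id: [100.0]}, index=["f1"]))
        out = normalize_osmolality(matrix, design_samples)
        assert out.values.loc["f1", sample_id] == pytest.approx(100.0 / 500.0)
        assert out.basis == "osmolality_normalized"

    def test_matches_independent_recomputation_on_cohort(self, small_cohort):
        from uromet.io_tables import samples_frame
        sdf = samples_frame(small_cohort.samples)
        out = normalize_osmolality(small_cohort.lcms, small_cohort.samples)
        for sample_id in out.values.columns:
            osmo = float(sdf.loc[sample_id, "osmolality"])
            np.testing.assert_allclose(
                out.values[sample_id],
                small_cohort.lcms.values[sample_id] / osmo)

    def test_dilution_invariance(self, design_samples):
        """Diluting a sample scales both its concentrations and its
        osmolality; normalization removes the dilution entirely."""
        rec = design_samples[0]
        diluted = [SampleRecord(**{**rec.__dict__, "osmolality": rec.osmolality / 3}),
                   *design_samples[1:]]
        matrix = MeasurementMatrix("NMR", "raw", pd.DataFrame(
            {rec.sample_id: [30.0, 9.0]}, index=["f1", "f2"]))
        diluted_matrix = MeasurementMatrix("NMR", "raw", matrix.values / 3)
        a = normalize_osmolality(matrix, design_samples)
        b = normalize_osmolality(diluted_matrix, diluted)
        pd.testing.assert_frame_equal(a.values, b.values)

    def test_untargeted_platform_rejected(self, small_cohort):
        with pytest.raises(ValidationError, match="targeted"):
            normalize_osmolality(small_cohort.untargeted, small_cohort.samples)


class TestExcretion:
    def test_amount_is_concentration_times_volume(self, design_samples):
        rec = next(r for r in design_samples if r.timepoint == "U01")
        matrix = MeasurementMatrix("LC-MS", "raw", pd.DataFrame(
            {rec.sample_id: [50.0]}, index=["f1"]))
        out = compute_excretion(matrix, design_samples, timepoints=["U01"])
        assert out["amount"].iloc[0] == pytest.approx(50.0 * 0.5)

    def test_cumulative_equals_sum_of_phases_everywhere(self, small_cohort):
        merged, _ = merge_platforms(small_cohort.nmr, small_cohort.lcms,
                                    small_cohort.duplicate_ids)
        out = compute_excretion(merged, small_cohort.samples)
        phases = out[out["phase"] != "cumulative"]
        sums = phases.groupby(["feature_id", "subject_id", "trial"])["amount"].sum()
        cumul = out[out["phase"] == "cumulative"].set_index(
            ["feature_id", "subject_id", "trial"])["amount"]
        assert len(cumul) == len(sums)
        np.testing.assert_allclose(cumul.sort_index(), sums.sort_index())

    def test_spot_samples_rejected(self, design_samples, small_cohort):
        with pytest.raises(ValidationError, match="U00"):
            compute_excretion(small_cohort.lcms, small_cohort.samples,
                              timepoints=["U00"])


class TestMergePlatforms:
    def test_duplicates_counted_once_with_lcms_preferred(self, small_cohort):
        merged, report = merge_platforms(small_cohort.nmr, small_cohort.lcms,
                                         small_cohort.duplicate_ids)
        n_expected = (len(small_cohort.nmr.values)
                      + len(small_cohort.lcms.values)
                      - len(small_cohort.duplicate_ids))
        assert len(merged.values) == n_expected
        for dup in small_cohort.duplicate_ids:
            np.testing.assert_allclose(merged.values.loc[dup],
                                       small_cohort.lcms.values.loc[dup])

    def test_identical_duplicate_has_unit_r2(self, small_cohort):
        nmr_copy = MeasurementMatrix(
            "NMR", "raw",
            small_cohort.lcms.values.loc[small_cohort.duplicate_ids].copy())
        _, report = merge_platforms(nmr_copy, small_cohort.lcms,
                                    small_cohort.duplicate_ids)
        assert (report["r2"] > 0.999999).all()

    def test_uncorrelated_duplicate_triggers_warning(self, caplog, design_samples):
        rng = np.random.default_rng(0)
        cols = [r.sample_id for r in design_samples]
        nmr = MeasurementMatrix("NMR", "raw", pd.DataFrame(
            rng.lognormal(size=(1, len(cols))), index=["dup"], columns=cols))
        lcms = MeasurementMatrix("LC-MS", "raw", pd.DataFrame(
            rng.lognormal(size=(1, len(cols))), index=["dup"], columns=cols))
        with caplog.at_level(logging.WARNING):
            _, report = merge_platforms(nmr, lcms, ["dup"])
        assert report["warn"].iloc[0]
        assert report["r2"].iloc[0] < 0.3
        assert any("agreement" in rec.message for rec in caplog.records)

    def test_unknown_duplicate_rejected(self, small_cohort):
        with pytest.raises(ValidationError, match="absent"):
            merge_platforms(small_cohort.nmr, small_cohort.lcms, ["ghost"])


def _drift_fixture(drift=None, n_study=40, n_qc=8, base=1000.0):
    """One-feature untargeted matrix over a synthetic run with QCs."""
    records, values = [], {}
    order = 0
    qc_positions = np.linspace(0, n_study + n_qc - 1, n_qc).astype(int)
    k = 0
    for pos in range(n_study + n_qc):
        order += 1
        curve = drift(order) if drift else 1.0
        if pos in qc_positions:
            k += 1
            sid = f"QC{k:02d}"
            records.append(SampleRecord(sample_id=sid, injection_order=order,
                                        is_qc=True))
            values[sid] = base * curve
        else:
            i = pos
            sid = f"st{i:03d}"
            records.append(SampleRecord(
                sample_id=sid, subject_id=f"P{i % 8:02d}",
                visit="V1", trial="CME" if i % 2 else "CVE",
                timepoint="U00", osmolality=500.0,
                injection_order=order))
            values[sid] = base * curve
    matrix = MeasurementMatrix("GCxGC-MS", "raw",
                               pd.DataFrame(values, index=["f1"]))
    return matrix, records


class TestDriftCorrection:
    def test_flat_qc_trace_is_identity(self):
        matrix, records = _drift_fixture(drift=None)
        out, report = qc_drift_correct(matrix, records)
        np.testing.assert_allclose(out.values.to_numpy(),
                                   matrix.values.to_numpy(), rtol=1e-9)
        assert report["corrected"].all()

    def test_linear_drift_reduces_qc_cv_by_half(self):
        matrix, records = _drift_fixture(drift=lambda o: 1.0 + 0.004 * o)
        qc_cols = [r.sample_id for r in records if r.is_qc]
        before = matrix.values[qc_cols].to_numpy().ravel()
        out, _ = qc_drift_correct(matrix, records)
        after = out.values[qc_cols].to_numpy().ravel()
        cv = lambda x: np.std(x) / np.mean(x)
        assert cv(after) <= 0.5 * cv(before)

    def test_too_few_detected_qcs_passes_through_flagged(self):
        matrix, records = _drift_fixture(drift=lambda o: 1.0 + 0.004 * o)
        vals = matrix.values.copy()
        qc_cols = [r.sample_id for r in records if r.is_qc]
        vals.loc["f1", qc_cols[3:]] = np.nan  # only 3 detected QCs
        sparse = MeasurementMatrix("GCxGC-MS", "raw", vals)
        out, report = qc_drift_correct(sparse, records, min_qc=5)
        assert not report["corrected"].iloc[0]
        assert "uncorrected" in report["flags"].iloc[0]
        study_cols = [r.sample_id for r in records if not r.is_qc]
        pd.testing.assert_frame_equal(out.values[study_cols], vals[study_cols])

    def test_missingness_pattern_preserved(self, small_cohort):
        out, _ = qc_drift_correct(small_cohort.untargeted, small_cohort.samples)
        pd.testing.assert_frame_equal(out.values.isna(),
                                      small_cohort.untargeted.values.isna())

    def test_no_qc_samples_is_an_error(self):
        matrix, records = _drift_fixture()
        study = [r for r in records if not r.is_qc]
        study_matrix = MeasurementMatrix(
            "GCxGC-MS", "raw", matrix.values[[r.sample_id for r in study]])
        with pytest.raises(ValidationError, match="QC"):
            qc_drift_correct(study_matrix, study)


class TestLocalLinearSmoother:
    def test_exact_on_linear_data(self):
        x = np.arange(1.0, 12.0)
        xvals = np.linspace(-2.0, 14.0, 40)
        S = local_linear_smoother(x, xvals, span=0.75)
        y = 3.0 + 0.5 * x
        np.testing.assert_allclose(S @ y, 3.0 + 0.5 * xvals, rtol=1e-9)

    def test_constant_maps_to_constant(self):
        x = np.arange(1.0, 9.0)
        S = local_linear_smoother(x, np.linspace(0, 10, 25), span=0.6)
        np.testing.assert_allclose(S @ np.full(8, 7.0), 7.0, rtol=1e-12)

    def test_agrees_with_statsmodels_lowess(self):
        rng = np.random.default_rng(13)
        x = np.sort(rng.uniform(0, 100, 15))
        y = 5.0 + 0.02 * x + rng.normal(0, 0.3, 15)
        xvals = np.sort(rng.uniform(0, 100, 30))
        ours = local_linear_smoother(x, xvals, span=0.75) @ y
        ref = sm_lowess(y, x, frac=0.75, it=0, xvals=xvals)
        np.testing.assert_allclose(ours, ref, rtol=1e-6)
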