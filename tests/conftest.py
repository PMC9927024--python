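import numpy as np
import pandas as pd
import pytest

from uromet.io_tables import TIMEPOINTS, SampleRecord
from uromet.synthetic import SimConfig, generate_cohort


@pytest.fixture(scope="session")
def small_config():
    return SimConfig(seed=11, n_subjects=8, n_targeted=12, n_lcms=5,
                     n_shared=2, n_untargeted=60)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_cohort(small_config)


@pytest.fixture(scope="session")
def noise_free_cohort():
    cfg = SimConfig(seed=7, n_subjects=8, n_targeted=12, n_lcms=5,
                    n_shared=2, n_untargeted=40).noise_free()
    return generate_cohort(cfg)


def make_design_samples(n_subjects=4, osmolality=500.0, volume=0.5):
    """Hand-built complete crossover design with constant covariates."""
    records = []
    for i in range(n_subjects):
        subject = f"P{i + 1:02d}"
        order = ("CME", "CVE") if i % 2 == 0 else ("CVE", "CME")
        for visit, trial in zip(("V1", "V2"), order):
            for tp in TIMEPOINTS:
                records.append(SampleRecord(
                    sample_id=f"{subject}_{trial}_{tp}",
                    subject_id=subject, visit=visit, trial=trial, timepoint=tp,
                    urine_volume=volume if tp in ("U01", "U02", "U03") else None,
                    osmolality=osmolality))
    return records


@pytest.fixture
def design_samples():
    return make_design_samples()
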