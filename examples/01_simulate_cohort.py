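"""Generate a synthetic crossover cohort and inspect its structure.

The simulator emulates a randomized two-trial crossover exercise study:
every subject performs a moderate (CME) and a vigorous (CVE) trial, urine
is sampled at five time points per trial (U00 baseline, U01-U03 timed
post-exercise collection phases, U04 next morning), and three analytical
platforms measure the samples. Ground-truth effect labels are stored
alongside the data, so any downstream analysis can be scored.
"""

from uromet import SimConfig, generate_cohort, samples_frame

config = SimConfig(seed=1)
cohort = generate_cohort(config)

sdf = samples_frame(cohort.samples)
study = sdf[~sdf["is_qc"]]
print(f"study samples: {len(study)} "
      f"({config.n_subjects} subjects x 2 trials x 5 time points)")
print(f"QC injections: {int(sdf['is_qc'].sum())} interleaved in the run order")
print(f"targeted matrices: NMR {cohort.nmr.values.shape}, "
      f"LC-MS {cohort.lcms.values.shape} "
      f"({len(cohort.duplicate_ids)} metabolites measured by both)")
print(f"untargeted matrix: {cohort.untargeted.values.shape}, "
      f"{cohort.untargeted.values.isna().mean().mean():.1%} cells below detection")

osmo = study.groupby("timepoint")["osmolality"].mean()
print("\nmean osmolality by time point (mOsm/kg):")
print(osmo.round(0).to_string())

active = cohort.truth.labels[cohort.truth.labels["template"] != "null"]
print(f"\nground truth: {len(active)} of {len(cohort.truth.labels)} features "
      f"carry an exercise effect template")
print(active["template"].value_counts().to_string())

# The osmolality profile falls from U00 to U03 (post-exercise rehydration
# dilutes the urine); the active features are the targets the analysis
# pipeline should recover.
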