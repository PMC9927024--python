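"""Two-step triage of untargeted features by detection frequency.

Features detected in more than 50% of samples in at least nine of the ten
(trial, timepoint) subgroups enter formal statistics; sparser features
become heuristic review candidates only when a main comparison shows a
strong detection-frequency contrast (< 30% vs > 75%) together with an
imputed median fold change beyond 2-fold.
"""

from uromet import SimConfig, generate_cohort, qc_drift_correct, triage

cohort = generate_cohort(SimConfig(seed=1))
corrected, _ = qc_drift_correct(cohort.untargeted, cohort.samples)

result = triage(corrected, cohort.samples)
print(result["route"].value_counts().to_string())

candidates = result[result["route"] == "heuristic_candidate"]
print(f"\n{len(candidates)} heuristic candidates for visual review:")
for row in candidates.itertuples(index=False):
    print(f"  {row.feature_id}: detected >50% in {row.n_subgroups_detected} "
          f"subgroups; triggers: {row.triggers}")

# The statistical route carries the bulk of the features; candidates are
# near-absent features whose appearance/disappearance tracks an exercise
# comparison strongly enough to warrant a human look at their plots.
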