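"""Run the comparison scheme: pre-tests, then the six main comparisons.

Within-group comparisons (U00 vs U01/U02/U03 per trial) use paired
Wilcoxon signed-rank tests on osmolality-normalized concentrations;
between-group comparisons (CME vs CVE at matched time points) are
additionally run on absolute and cumulative excretion. Benjamini-Hochberg
FDR is applied within pooled within- and between-group families.
"""

import numpy as np

from uromet import (
    SimConfig,
    compute_excretion,
    generate_cohort,
    merge_platforms,
    normalize_osmolality,
    run_main_comparisons,
    run_pretests,
)

cohort = generate_cohort(SimConfig(seed=1))
merged, _ = merge_platforms(cohort.nmr, cohort.lcms, cohort.duplicate_ids)
normalized = normalize_osmolality(merged, cohort.samples)
excretion = compute_excretion(merged, cohort.samples)

pretests = run_pretests(normalized, None, cohort.samples)
warned = pretests[pretests["flags"].str.contains("pretest_warning")]
print(f"pre-tests: {len(pretests)} results, {len(warned)} flagged "
      f"(baseline and carry-over comparability)")

results = run_main_comparisons(normalized, None, excretion, cohort.samples)
significant = results[(results["q_fdr"] < 0.05)]
print(f"main comparisons: {len(results)} tests, "
      f"{len(significant)} significant after FDR")

top = significant.copy()
top["abs_log_fc"] = np.abs(np.log(top["median_fc"]))
top = top.nlargest(5, "abs_log_fc")
print("\nstrongest significant comparisons:")
for row in top.itertuples(index=False):
    print(f"  {row.feature_id} {row.comparison_id} [{row.basis}]: "
          f"FC={row.median_fc:.2f}, q={row.q_fdr:.2e}")

# Each line is one metabolite in one comparison: FC > 1 means higher after
# exercise (within-group) or higher on the vigorous trial (between-group).
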