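# uromet

Analysis pipeline for crossover urinary-metabolomics exercise studies,
plus a seeded synthetic-cohort generator with known ground truth.

## The problem

In a randomized crossover design, each subject performs two acute
endurance-exercise trials — continuous moderate (CME) and continuous
vigorous (CVE) — and urine is collected at five time points per trial: a
fasting pre-exercise spot sample (U00), three complete timed post-exercise
collection phases (U01: to 45 min; U02: 45–105 min; U03: 105–195 min), and
a next-morning spot sample (U04). Metabolites are measured by targeted NMR
and LC-MS (absolute concentrations, µmol/L) and by untargeted GC×GC-MS
(relative intensities with detection-limit missingness and run-order
drift). The scientific questions are which urinary metabolites respond to
exercise at all (*exercise-responsive*) and which respond more strongly to
the vigorous trial (*intensity-dependent*).

The analysis has to cope with three nuisance structures that dominate raw
urine data: dilution (post-exercise rehydration drops osmolality several
fold, diluting every solute), instrument drift in long untargeted runs,
and value-dependent missingness in untargeted features. `uromet`
implements the full workflow as a tested library for anyone running or
reanalyzing this class of study.

## The method

For a metabolite $f$, trial $t \in \{\mathrm{CME}, \mathrm{CVE}\}$ and
time point $u$:

- **Dilution handling** — concentrations are normalized to osmolality,
  $\tilde c = c / \mathrm{osm}$; for the collection phases, absolute
  excretion $m = c \times V$ (µmol) and cumulative excretion
  $\sum_{u \in \{U01,U02,U03\}} m_u$ are computed from the collected
  volumes $V$.
- **Drift correction** — per untargeted feature, a tricube-weighted local
  linear (LOWESS, degree 1) trend $g(\text{order})$ is fitted to the
  interleaved pooled-QC injections; study values are divided by
  $g(\text{order})/r$ with $r$ the median QC level.
- **Feature triage** — untargeted features with detection frequency
  $> 0.5$ in at least 9 of the 10 (trial × time point) subgroups enter
  statistics; sparser features become review candidates when a main
  comparison pairs frequencies $< 0.30$ against $> 0.75$ with an imputed
  median fold change $> 2$ or $< 0.5$.
- **Testing** — paired Wilcoxon signed-rank tests within trials (U00 vs
  U01/U02/U03) and between trials at matched time points (unpaired
  rank-sum for untargeted features); exact null distributions for small
  untied samples, normal approximation with tie/continuity corrections
  otherwise; Benjamini–Hochberg FDR within pooled within-group and
  between-group families.
- **Relevance classification** — a comparison is relevant iff
  $q < 0.05$ **and** median FC $> 1.5$ or $< 2/3$ (targeted) respectively
  $> 2.0$ or $< 0.5$ (untargeted). Any relevant within-trial comparison
  makes a feature exercise-responsive for that trial; any relevant
  between-trial comparison (concentration or excretion basis) makes it
  intensity-dependent. Venn overlaps and a z-scored subgroup-median
  heatmap matrix summarize the calls.

The synthetic cohort draws log-normal abundances with subject random
effects, multiplicative effect templates (transient/persistent, up/down)
whose log fold change is multiplied by an intensity-scaling factor on the
vigorous trial, a falling osmolality time course with proportional
dilution of targeted concentrations, logistic left-censoring around
per-feature detection limits, and per-feature drift curves carried by QC
injections. Ground-truth labels come from thresholding the noise-free
fold changes with the same relevance bounds.

## Worked example

```python
from uromet import SimConfig, generate_cohort, run_study

cohort = generate_cohort(SimConfig(seed=1))
result = run_study(cohort.samples, nmr=cohort.nmr, lcms=cohort.lcms,
                   untargeted=cohort.untargeted,
                   feature_meta=cohort.feature_meta,
                   duplicate_map=cohort.duplicate_ids, seed=1)
print(result.counts)
```

prints

```
{'n_samples': 160, 'n_targeted': 44, 'n_untargeted_detected': 608,
 'n_statistical_route': 591, 'n_heuristic_candidates': 5, 'n_dropped': 12,
 'n_significant_features': 184, 'n_relevant': 186}
```

Of the 608 simulated untargeted features, 591 are detected often enough
for formal statistics, 5 sparse features trigger the heuristic review
route, and 12 are dropped. Jointly with the 44 targeted metabolites, 186
features end up relevant — close to the 196 features that truly carry an
effect in this cohort; scoring the calls against the stored ground truth
gives sensitivities of 0.92–0.95 per relevance label with zero false
discoveries (see `examples/05_classify_and_report.py`). The
`examples/` directory walks through each stage separately; the `uromet`
console script (`uromet simulate/validate/run/report`) exposes the same
pipeline from the shell.

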