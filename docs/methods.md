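# Methods

This note records the statistical model behind `uromet`, the conventions
and tunable parameters of each stage, what the synthetic-cohort generator
does and does not emulate, and the design choices made where several
defensible options existed.

## Study design and data model

The unit of design is a (subject, trial, timepoint) cell: each subject
performs a moderate (CME) and a vigorous (CVE) endurance-exercise trial
in randomized visit order, with urine at U00 (fasting baseline spot),
U01–U03 (complete timed post-exercise collections, the only time points
with measured volume, in liters) and U04 (next-morning fasting spot).
Osmolality (mOsm/kg) is required on every study sample. Pooled-urine QC
injections live in the same sample table with `is_qc=True`, an injection
order, and no design coordinates. Validation is total: malformed tables
raise typed `ValidationError`s rather than being coerced.

Measurement matrices are feature × sample with a platform tag and a
*basis* recording their position in the preprocessing DAG
(`raw → osmolality_normalized | absolute_excretion → cumulative_excretion | drift_corrected`);
illegal transitions are rejected. Missing cells are only legal for the
untargeted GC×GC-MS platform.

## Preprocessing

**Osmolality normalization** divides each targeted concentration by its
sample's osmolality. Because the urine of a well-hydrated subject after
exercise can be several-fold more dilute than at baseline, this step is
what makes within-subject comparisons across time points meaningful.
Untargeted intensities are *not* normalized: those samples are diluted to
a common osmolality (60 mOsm/kg) before GC×GC-MS acquisition, so dilution
is equalized upstream; normalizing them again would double-correct.
Conversely, targeted metabolites are never drift-corrected — they come
from calibrated quantification.

**Excretion** is concentration × collected volume per phase (µmol), with
one cumulative record per (feature, subject, trial) summing U01–U03;
cumulative records are only emitted when all three phases are present.

**Platform merge**: metabolites quantified by both targeted platforms are
kept once with the LC-MS values (the more sensitive and less
peak-assignment-dependent platform). The between-platform R² over shared
samples is reported per duplicate; values below the configurable floor
(default 0.87) log a warning but never abort, since disagreement is a
data-quality observation, not a pipeline error.

**QC drift correction**: per untargeted feature, a non-robust
tricube-weighted local *linear* regression of QC intensity on injection
order (span = 0.75 of QC points, `int(span·n)` nearest neighbors per
evaluation point) is evaluated at every injection order, and study values
are divided by trend/reference, reference = median QC intensity. The
correction is multiplicative because chromatographic response drift acts
proportionally on strictly positive intensities; an additive variant
would produce negative values at low intensities. Correction factors are
clipped to [0.2, 5] to prevent blow-ups when extrapolating past the last
QC; clipped features are flagged. Features with fewer than `min_qc`
(default 5) detected QCs pass through unchanged, flagged `uncorrected`.
The smoother is expressed as a smoother matrix (predictions are linear in
the QC values), so one matrix serves every feature sharing the full QC
grid; the fit is exact for linear traces and the identity for constant
traces, which the tests verify to 1e-9. Missingness is never altered.

## Feature triage

Detection frequency is the exact non-missing fraction per feature in each
of the ten (trial × timepoint) subgroups. A feature enters the
statistical route iff its frequency strictly exceeds 0.5 in at least nine
of the ten subgroups. Remaining features become heuristic review
candidates iff, for one of the main subgroup comparisons, one member has
frequency strictly below 0.30 and the other strictly above 0.75 *and* the
imputed median fold change between the two subgroups exceeds 2.0 or falls
below 0.5. We read the low/high frequency pair as applying to the two
members of a compared pair (the natural reading given that candidates are
then inspected per comparison); a config switch (`mode="any"`) exposes
the alternative any-two-subgroups reading. Missing values entering the
heuristic fold change are imputed with half the feature's global minimum
detected intensity — the standard left-censor surrogate — because this
route exists precisely for near-absent features where complete-case
fold changes would be undefined. The statistical route never imputes.
The final human step (inspecting candidate box/line plots for
"interesting vs random" behavior) is supported by automatically rendered
per-candidate plots, not automated away.

## Testing and classification

Within-group comparisons (U00 vs U01/U02/U03 per trial) and between-group
comparisons (CME vs CVE at U01/U02/U03) run on osmolality-normalized
concentrations (targeted) or drift-corrected intensities (untargeted);
between-group comparisons additionally run on absolute excretion per
phase and on cumulative excretion for targeted metabolites. Four advisory
pre-tests check baseline comparability (U00 across visits and across
trials) and carry-over (U00 vs U04 per trial); failures are logged as
flags and the pipeline proceeds.

Tests are Wilcoxon signed-rank (paired; zeros dropped per Wilcoxon's
convention, flagged when >20% of pairs are zero; exact null distribution
for n ≤ 25 without ties, else normal approximation with tie and
continuity corrections) and Wilcoxon rank-sum (exact for
n₁+n₂ ≤ 20 untied, else corrected normal approximation). Targeted
comparisons are paired by subject; untargeted comparisons default to
unpaired, reflecting that sample exclusions in practice often break the
pairing (a `paired_untargeted` switch covers complete data). All-zero
difference vectors return p = 1 flagged `degenerate`; groups with fewer
than 3 values are `untestable` and excluded from FDR families. The exact
null distributions are cached dynamic programs shared across features,
and whole feature matrices are tested vectorized; the vectorized path is
asserted equal to the single-vector path, which in turn is asserted equal
to brute-force enumeration and to scipy.

FDR is Benjamini–Hochberg (via statsmodels, with a hand-written step-up
oracle in the tests). Families: all within-group p-values pooled into one
family and all between-group p-values (all bases) into another,
separately for targeted and untargeted features; each pre-test is its own
family. Pooling across the six within comparisons (rather than per
comparison) is the stricter and simpler reading of "combined" correction;
`fdr_scope="per_comparison"` exposes the alternative.

Median fold change is the median of per-subject ratios when pairing
exists (more efficient, uses the design) and the ratio of group medians
otherwise; the two coincide under constant ratios. Relevance is the joint
criterion q < 0.05 **and** FC > 1.5 or FC < 2/3 (targeted; the lower
bound is the exact rational 2/3, not 0.66) respectively FC > 2.0 or
FC < 0.5 (untargeted) — all comparisons strict, bounds reciprocal. A
feature relevant only on an excretion basis still counts as
intensity-dependent: excretion differences are findings in their own
right. Heuristic-route candidates are relevant exactly when triage
flagged them and carry no q-value.

## Summaries

The heatmap matrix holds per-feature subgroup medians (detected values
only; no imputation in display) over the ten subgroups ordered CME
U00–U04 then CVE U00–U04 — U04 columns included, since the displays cover
all time points — z-transformed across the row with the population SD
(ddof 0; a constant row becomes all zeros, keeping degenerate rows
bounded). Rows with fewer than two non-missing subgroup medians are
flagged and left untransformed. Rows are grouped by major pathway
(pathways ordered by number of relevant features, then name) and sorted
within a group by decreasing U01(CVE)/U00(CVE) median ratio. Venn counts
are computed over the three label sets after mapping feature ids through
an identity map (display name by default) so a metabolite detected on two
platforms is counted once. The run manifest records a canonical config
hash, the seed, library versions and per-stage counts; two runs with the
same config differ only in the timestamp.

## Synthetic cohorts

The generator emulates the *statistical structure* the analysis assumes,
not urine chemistry. Log abundance of feature $f$ in sample $s$ (subject
$j$, trial $t$, timepoint $u$) is

$\log v = \mu_f + b_{fj} + \beta\,\log(\mathrm{osm}_s/\mathrm{osm}_{ref}) + \log\mathrm{fc}_f(t,u) + \varepsilon$,

with $b \sim N(0, \sigma_{subj}^2)$ (default 0.4),
$\varepsilon \sim N(0, \sigma_{res}^2)$ (default 0.3, natural-log scale —
within-subject CVs around 30%, typical of urinary metabolites), and
$\mu_f$ drawn per feature (targeted around 50 µmol/L, spread 1 log unit).

*Dilution*: the term $\beta \log(\mathrm{osm}/\mathrm{osm}_{ref})$
($\beta = 1$, targeted features only) makes concentrations track
osmolality, as total-solute physiology dictates; osmolality normalization
then removes dilution exactly, and a generator without this term would
turn the hydration time course itself into a spurious effect on every
null feature. Untargeted intensities carry no dilution term (equalized
upstream, see above). The osmolality time course declines U00 → U03
(means 700/500/350/250, back to 650 at U04), with the extra water intake
on the vigorous trial modeled as a factor 0.8 on U03 osmolality and its
reciprocal on U03 volume — more dilute urine, larger volume, identical
solute excretion, so excretion comparisons of null features stay null.
Volumes rise over the collection phases (0.35/0.45/0.55 L).

*Effects* are multiplicative templates over time points
(`immediate_transient_up` U01 ×3; `persistent_up` ×3/×2.5/×2.2;
`late_down` U02 ×0.45, U03 ×⅓; `persistent_down` ×⅓ throughout; `null`),
assigned 70% null / 7.5% each active by largest-remainder allocation and
seeded permutation. On the vigorous trial the log fold change is
multiplied by `intensity_scaling` (default 2), so a single knob sets the
between-trial contrast: with a U01 fold change of 3, the CVE fold change
is 9 and the noise-free between-trial ratio is 3.

*Detection*: each untargeted cell survives with probability
logistic(slope · (log v − LOD_f)), slope 1.2 per log unit, LOD_f drawn
3.0 ± 1.0 log units below the feature mean. These defaults put overall
detection near 94% and route roughly 2–4% of features away from the
statistical path, matching the proportions typical of GC×GC-MS urine
feature tables. Censoring is value-dependent (left-censoring-like), which
is exactly the missingness the frequency filter must tolerate.

*Drift and QCs*: injection order is a seeded permutation of the study
samples with one QC before every 16 study injections plus a closing QC
(≥5 per run). Per feature, the drift curve is
1 + a·(centered order) + m·sin(2π·order/period + φ) with a ~ N(0, 0.08),
m ~ N(0, 0.04), period = half the run, clipped at 0.2; study values are
multiplied by it after censoring (drift does not alter detection), and QC
values are the feature's reference level × drift × 3% log-normal noise.

Ground-truth labels are obtained by thresholding the noise-free fold
change profile of every comparison (including the excretion-weighted
between-trial ratios) with the classifier's own strict bounds, so truth
and calls share one definition of relevance. With all noise parameters
zero (`SimConfig.noise_free()`), the pipeline recovers every label
exactly — a property the tests assert.

**What the generator does not emulate:** correlated metabolite panels
(features are independent given the design), batch/day structure beyond
the smooth run-order drift, non-log-normal heavy tails, missingness from
coelution or annotation failure (only detection-limit censoring),
drop-out of whole samples, and any real biochemistry (templates are
shapes, not pathways). Passing recovery tests therefore demonstrate that
the pipeline's logic is correct under its own assumptions, not that those
assumptions hold for any particular instrument or cohort.

## Numerical choices and validation sizes

Exact-test p-values are twice the smaller tail probability, capped at 1;
continuity corrections clamp at zero. The acceptance-style validation
uses problem sizes chosen to exercise the full design while keeping the
suite fast on one core: 200 global-null replicate cohorts (16 subjects,
44 targeted + 500 untargeted features) for type-I-error and relevance
control, three seeded active cohorts at the default study dimensions for
sensitivity/false-discovery recovery, and enumeration oracles at n ≤ 8
(signed-rank, 2ⁿ sign patterns) and n₁+n₂ ≤ 12 (rank-sum, all labelings).

## Known limitations

Unpaired between-trial tests ignore the crossover pairing for untargeted
features (by design, mirroring practical sample exclusions), costing
power; repeated-measures or mixed-model analysis is out of scope. The
heuristic route's final judgment is human. The drift model assumes the
QC pool behaves like study samples under drift (shared multiplicative
factor); matrix-dependent drift would violate this. Fold-change
thresholds are fixed per platform class, not per-feature precision.
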