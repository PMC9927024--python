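"""Nonparametric testing machinery and the crossover comparison scheme.

The analysis compares urinary metabolite levels within each trial against
the pre-exercise baseline (within-group comparisons: U00-U01, U00-U02,
U00-U03, per trial) and between the two trials at matched post-exercise
time points (between-group comparisons: U01-U01, U02-U02, U03-U03; for
targeted metabolites additionally on absolute excretion per collection
phase and on cumulative excretion). Four pre-tests check that baselines
are comparable across visits and trials and that next-morning levels
returned to baseline.

Tests are Wilcoxon signed-rank (paired) and Wilcoxon rank-sum /
Mann-Whitney (unpaired). Exact null distributions are used for small
samples without ties (signed-rank: n <= 25; rank-sum: n1 + n2 <= 20) and a
normal approximation with tie and continuity corrections otherwise. Exact
distributions are computed once per sample size by dynamic programming and
cached, so testing hundreds of features costs little more than ranking
them. Benjamini-Hochberg FDR adjustment is applied within comparison
families (all within-group p-values pooled into one family, all
between-group p-values into another, separately for targeted and
untargeted features; pre-test families are corrected separately).
Effect sizes are median fold changes: the median of per-subject ratios
when pairing exists, the ratio of group medians otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

from .io_tables import COLLECTION_PHASES, MeasurementMatrix, SampleRecord, samples_frame

__all__ = [
    "TestResult",
    "FoldChangeResult",
    "ComparisonSpec",
    "wilcoxon_signed_rank",
    "wilcoxon_rank_sum",
    "bh_fdr",
    "median_fold_change",
    "main_comparison_scheme",
    "pretest_scheme",
    "run_pretests",
    "run_main_comparisons",
]


@dataclass(frozen=True)
class TestResult:
    p: float
    n: int
    statistic: float
    method: str  # "exact" | "approx" | "degenerate" | "untestable"
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class FoldChangeResult:
    fc: float
    n: int
    flags: tuple[str, ...] = ()

    @property
    def direction(self) -> str:
        if not np.isfinite(self.fc) or self.fc == 1.0:
            return "none"
        return "up" if self.fc > 1.0 else "down"


# ---------------------------------------------------------------------------
# exact null distributions (cached dynamic programs)

@lru_cache(maxsize=64)
def _signed_rank_cdf(n: int) -> np.ndarray:
    """Counts c[w] of sign assignments with positive-rank sum w, n untied ranks."""
    wmax = n * (n + 1) // 2
    c = np.zeros(wmax + 1)
    c[0] = 1.0
    for i in range(1, n + 1):
        c[i:] += c[:-i].copy()
    return np.cumsum(c) / 2.0 ** n


@lru_cache(maxsize=256)
def _rank_sum_cdf(n1: int, n2: int) -> np.ndarray:
    """CDF of the rank sum of group 1 (sizes n1, n2, no ties).

    dp[k][s] = number of k-subsets of ranks 1..N with sum s.
    """
    N = n1 + n2
    smax = sum(range(N - n1 + 1, N + 1))
    dp = np.zeros((n1 + 1, smax + 1))
    dp[0, 0] = 1.0
    for r in range(1, N + 1):
        for k in range(min(n1, r), 0, -1):
            dp[k, r:] += dp[k - 1, :-r]
    counts = dp[n1]
    total = counts.sum()
    return np.cumsum(counts) / total


def _two_sided_exact(cdf: np.ndarray, stat: int) -> float:
    lo = cdf[stat]
    hi = 1.0 - (cdf[stat - 1] if stat > 0 else 0.0)
    return min(1.0, 2.0 * min(lo, hi))


def _norm_sf(z: np.ndarray | float):
    return 0.5 * erfc(np.asarray(z) / np.sqrt(2.0))


# ---------------------------------------------------------------------------
# vectorized blocks: identical results to the single-vector tests, computed
# for a whole feature matrix at once (shared exact null distribution, C-level
# ranking); rows needing special handling fall back to the scalar path.

def _signed_rank_block(diffs: np.ndarray, exact_max_n: int = 25):
    """Row-wise Wilcoxon signed-rank p-values for a features × pairs
    difference matrix. Returns (p, n, flags)."""
    diffs = np.asarray(diffs, dtype=float)
    n_rows, n_cols = diffs.shape
    p = np.empty(n_rows)
    n_used = np.full(n_rows, n_cols)
    flags: list[tuple[str, ...]] = [()] * n_rows
    finite = ~np.isnan(diffs)
    absd = np.abs(diffs)
    srt = np.sort(absd, axis=1)
    has_ties = (np.diff(srt, axis=1) == 0).any(axis=1)
    fast = (finite.all(axis=1) & ~(diffs == 0).any(axis=1) & ~has_ties
            & (n_cols <= exact_max_n))
    if fast.any():
        ranks = rankdata(absd[fast], axis=1)
        w_plus = (ranks * (diffs[fast] > 0)).sum(axis=1).astype(int)
        cdf = _signed_rank_cdf(n_cols)
        lo = cdf[w_plus]
        hi = 1.0 - np.where(w_plus > 0, cdf[np.maximum(w_plus - 1, 0)], 0.0)
        p[fast] = np.minimum(1.0, 2.0 * np.minimum(lo, hi))
    for i in np.flatnonzero(~fast):
        res = wilcoxon_signed_rank(diffs[i], exact_max_n=exact_max_n)
        p[i], n_used[i], flags[i] = res.p, res.n, res.flags
    return p, n_used, flags


def _rank_sum_block(left: np.ndarray, right: np.ndarray,
                    exact_max_total: int = 20):
    """Row-wise Wilcoxon rank-sum p-values for two features × samples
    matrices. Returns (p, n, flags)."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    n1, n2 = left.shape[1], right.shape[1]
    N = n1 + n2
    pooled = np.concatenate([left, right], axis=1)
    n_rows = pooled.shape[0]
    p = np.empty(n_rows)
    n_used = np.full(n_rows, N)
    flags: list[tuple[str, ...]] = [()] * n_rows
    finite = ~np.isnan(pooled)
    srt = np.sort(pooled, axis=1)
    has_ties = (np.diff(srt, axis=1) == 0).any(axis=1)
    fast = finite.all(axis=1) & ~has_ties & (n1 >= 3) & (n2 >= 3)
    if fast.any():
        ranks = rankdata(pooled[fast], axis=1)
        r1 = ranks[:, :n1].sum(axis=1)
        if N <= exact_max_total:
            cdf = _rank_sum_cdf(n1, n2)
            r1i = r1.astype(int)
            lo = cdf[r1i]
            hi = 1.0 - np.where(r1i > 0, cdf[np.maximum(r1i - 1, 0)], 0.0)
            p[fast] = np.minimum(1.0, 2.0 * np.minimum(lo, hi))
        else:
            mean = n1 * (N + 1) / 2.0
            var = n1 * n2 * (N + 1) / 12.0  # untied rows: no tie correction
            z = np.maximum(np.abs(r1 - mean) - 0.5, 0.0) / np.sqrt(var)
            p[fast] = np.minimum(1.0, 2.0 * _norm_sf(z))
    for i in np.flatnonzero(~fast):
        res = wilcoxon_rank_sum(left[i], right[i], exact_max_total=exact_max_total)
        p[i], n_used[i], flags[i] = res.p, res.n, res.flags
    return p, n_used, flags


# ---------------------------------------------------------------------------
# single-vector tests

def wilcoxon_signed_rank(differences: Sequence[float], exact_max_n: int = 25) -> TestResult:
    """Two-sided Wilcoxon signed-rank test on paired differences.

    Zero differences are dropped before ranking (Wilcoxon's convention; a
    flag is raised when more than 20% of pairs are zeros). The exact null
    distribution is used when the number of nonzero differences is at most
    ``exact_max_n`` and the absolute differences are untied; otherwise a
    normal approximation with tie and continuity corrections. All
    differences zero (or none usable) yields p = 1.0 with a "degenerate"
    flag rather than an error.
    """
    d = np.asarray(differences, dtype=float)
    d = d[~np.isnan(d)]
    n_total = d.size
    d = d[d != 0.0]
    n = d.size
    flags: list[str] = []
    if n_total and n_total - n > 0.2 * n_total:
        flags.append("many_zeros")
    if n == 0:
        return TestResult(1.0, 0, np.nan, "degenerate", ("degenerate", *flags))
    if n < 3:
        flags.append("small_n")
    absd = np.abs(d)
    ranks = rankdata(absd)
    w_plus = float(ranks[d > 0].sum())
    has_ties = np.unique(absd).size < n
    if n <= exact_max_n and not has_ties:
        p = _two_sided_exact(_signed_rank_cdf(n), int(round(w_plus)))
        return TestResult(p, n, w_plus, "exact", tuple(flags))
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(absd, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - (tie_counts ** 3 - tie_counts).sum() / 48.0
    if var <= 0:
        return TestResult(1.0, n, w_plus, "degenerate", ("degenerate", *flags))
    z = max(abs(w_plus - mean) - 0.5, 0.0) / np.sqrt(var)
    p = min(1.0, float(2.0 * _norm_sf(z)))
    return TestResult(p, n, w_plus, "approx", tuple(flags))


def wilcoxon_rank_sum(
    left_values: Sequence[float],
    right_values: Sequence[float],
    exact_max_total: int = 20,
) -> TestResult:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact distribution for n_left + n_right <= ``exact_max_total`` without
    ties; normal approximation with tie and continuity corrections
    otherwise. Either group with fewer than 3 non-missing values marks the
    result "untestable" (p = NaN, excluded from FDR families).
    """
    x = np.asarray(left_values, dtype=float)
    y = np.asarray(right_values, dtype=float)
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    n1, n2 = x.size, y.size
    if n1 < 3 or n2 < 3:
        return TestResult(np.nan, n1 + n2, np.nan, "untestable", ("untestable",))
    pooled = np.concatenate([x, y])
    ranks = rankdata(pooled)
    r1 = float(ranks[:n1].sum())
    has_ties = np.unique(pooled).size < pooled.size
    N = n1 + n2
    if N <= exact_max_total and not has_ties:
        p = _two_sided_exact(_rank_sum_cdf(n1, n2), int(round(r1)))
        return TestResult(p, N, r1, "exact", ())
    mean = n1 * (N + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = (tie_counts ** 3 - tie_counts).sum() / (N * (N - 1.0))
    var = n1 * n2 / 12.0 * ((N + 1.0) - tie_term)
    if var <= 0:
        return TestResult(1.0, N, r1, "degenerate", ("degenerate",))
    z = max(abs(r1 - mean) - 0.5, 0.0) / np.sqrt(var)
    p = min(1.0, float(2.0 * _norm_sf(z)))
    return TestResult(p, N, r1, "approx", ())


def bh_fdr(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} m * p_(j) / j, capped at 1; order-preserving.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or (p <= 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in (0, 1] with no missing entries")
    return multipletests(p, method="fdr_bh")[1]


def median_fold_change(
    left: Sequence[float],
    right: Sequence[float],
    paired: bool,
) -> FoldChangeResult:
    """Median fold change of ``right`` relative to ``left``.

    Paired mode: median over subjects of per-subject ratios right/left
    (pairs with a missing member are dropped; at least 3 complete pairs
    required). Unpaired mode: median(right)/median(left) over non-missing
    values. A zero or empty denominator flags the result "undefined_fc".
    """
    x = np.asarray(left, dtype=float)
    y = np.asarray(right, dtype=float)
    if paired:
        ok = ~np.isnan(x) & ~np.isnan(y)
        x, y = x[ok], y[ok]
        if x.size < 3:
            return FoldChangeResult(np.nan, int(x.size), ("undefined_fc", "too_few_pairs"))
        if (x == 0).any():
            return FoldChangeResult(np.nan, int(x.size), ("undefined_fc",))
        return FoldChangeResult(float(np.median(y / x)), int(x.size))
    x = x[~np.isnan(x)]
    y = y[~np.isnan(y)]
    if x.size == 0 or y.size == 0:
        return FoldChangeResult(np.nan, int(x.size + y.size), ("undefined_fc",))
    mx = float(np.median(x))
    if mx == 0:
        return FoldChangeResult(np.nan, int(x.size + y.size), ("undefined_fc",))
    return FoldChangeResult(float(np.median(y)) / mx, int(x.size + y.size))


# ---------------------------------------------------------------------------
# comparison scheme

@dataclass(frozen=True)
class ComparisonSpec:
    """One subgroup comparison: selectors are (trial, timepoint) pairs.

    For pre-test 1 the selectors are visit-based and ``left``/``right``
    hold (visit, timepoint) instead; ``selector`` records which.
    """

    comparison_id: str
    family: str  # "pretest" | "within" | "between"
    left: tuple[str, str]
    right: tuple[str, str]
    paired: bool
    basis: str
    selector: str = "trial"  # "trial" | "visit"


def main_comparison_scheme(
    paired: bool, basis: str, include_excretion: bool = False
) -> list[ComparisonSpec]:
    """The six main subgroup comparisons (plus excretion comparisons for
    targeted metabolites): within-trial changes from baseline and
    between-trial contrasts at matched post-exercise time points."""
    specs = []
    for trial in ("CME", "CVE"):
        for tp in COLLECTION_PHASES:
            specs.append(ComparisonSpec(
                f"within_{trial}_U00_{tp}", "within",
                (trial, "U00"), (trial, tp), paired, basis))
    for tp in COLLECTION_PHASES:
        specs.append(ComparisonSpec(
            f"between_{tp}", "between", ("CME", tp), ("CVE", tp), paired, basis))
    if include_excretion:
        for tp in COLLECTION_PHASES:
            specs.append(ComparisonSpec(
                f"between_{tp}_excretion", "between",
                ("CME", tp), ("CVE", tp), paired, "absolute_excretion"))
        specs.append(ComparisonSpec(
            "between_cumulative_excretion", "between",
            ("CME", "cumulative"), ("CVE", "cumulative"), paired,
            "cumulative_excretion"))
    return specs


def pretest_scheme(paired: bool, basis: str) -> list[ComparisonSpec]:
    """Four pre-tests: baseline comparability across visits and trials, and
    baseline-vs-next-morning comparability within each trial."""
    return [
        ComparisonSpec("pretest_U00_V1_V2", "pretest", ("V1", "U00"), ("V2", "U00"),
                       paired, basis, selector="visit"),
        ComparisonSpec("pretest_U00_CME_CVE", "pretest", ("CME", "U00"), ("CVE", "U00"),
                       paired, basis),
        ComparisonSpec("pretest_CME_U00_U04", "pretest", ("CME", "U00"), ("CME", "U04"),
                       paired, basis),
        ComparisonSpec("pretest_CVE_U00_U04", "pretest", ("CVE", "U00"), ("CVE", "U04"),
                       paired, basis),
    ]


def _subgroup_sample_map(sdf: pd.DataFrame, sel: tuple[str, str], selector: str) -> pd.Series:
    """subject_id -> sample_id for one (trial|visit, timepoint) subgroup."""
    key, tp = sel
    col = "trial" if selector == "trial" else "visit"
    sub = sdf[(~sdf["is_qc"]) & (sdf[col] == key) & (sdf["timepoint"] == tp)]
    return sub.set_index("subject_id")["sample_id"]


def _comparison_arrays(
    values: pd.DataFrame, sdf: pd.DataFrame, spec: ComparisonSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Feature x observation arrays for one comparison; paired comparisons
    align columns by subject (subjects present in both subgroups)."""
    left_map = _subgroup_sample_map(sdf, spec.left, spec.selector)
    right_map = _subgroup_sample_map(sdf, spec.right, spec.selector)
    if spec.paired:
        subjects = sorted(set(left_map.index) & set(right_map.index))
        if not subjects:
            raise ValueError(f"comparison {spec.comparison_id}: no paired subjects")
        L = values[left_map[subjects].tolist()].to_numpy(dtype=float)
        R = values[right_map[subjects].tolist()].to_numpy(dtype=float)
    else:
        L = values[[s for s in left_map if s in values.columns]].to_numpy(dtype=float)
        R = values[[s for s in right_map if s in values.columns]].to_numpy(dtype=float)
    return L, R


def _fold_change_block(L: np.ndarray, R: np.ndarray, paired: bool):
    """Row-wise median fold changes matching :func:`median_fold_change`."""
    n_rows = L.shape[0]
    fc = np.full(n_rows, np.nan)
    flags: list[tuple[str, ...]] = [()] * n_rows
    if paired:
        ok = ~np.isnan(L) & ~np.isnan(R)
        n_pairs = ok.sum(axis=1)
        zero_left = ((L == 0) & ok).any(axis=1)
        good = (n_pairs >= 3) & ~zero_left
        with np.errstate(divide="ignore", invalid="ignore"):
            ratios = np.where(ok, R / L, np.nan)
        fc[good] = np.nanmedian(ratios[good], axis=1)
        for i in np.flatnonzero(~good):
            res = median_fold_change(L[i], R[i], paired=True)
            fc[i], flags[i] = res.fc, res.flags
    else:
        n_left = (~np.isnan(L)).sum(axis=1)
        n_right = (~np.isnan(R)).sum(axis=1)
        ml = np.full(n_rows, np.nan)
        mr = np.full(n_rows, np.nan)
        ml[n_left > 0] = np.nanmedian(L[n_left > 0], axis=1)
        mr[n_right > 0] = np.nanmedian(R[n_right > 0], axis=1)
        good = (n_left > 0) & (n_right > 0) & (ml != 0)
        fc[good] = mr[good] / ml[good]
        flags = [(() if g else ("undefined_fc",)) for g in good]
    return fc, flags


def _run_one_comparison(
    values: pd.DataFrame, sdf: pd.DataFrame, spec: ComparisonSpec, platform_class: str
) -> pd.DataFrame:
    L, R = _comparison_arrays(values, sdf, spec)
    if spec.paired:
        p, n_used, test_flags = _signed_rank_block(R - L)
    else:
        p, n_used, test_flags = _rank_sum_block(L, R)
    fc, fc_flags = _fold_change_block(L, R, spec.paired)
    with np.errstate(invalid="ignore"):
        direction = np.where(~np.isfinite(fc) | (fc == 1.0), "none",
                             np.where(fc > 1.0, "up", "down"))
    flags = [";".join(dict.fromkeys(tf + ff))
             for tf, ff in zip(test_flags, fc_flags)]
    return pd.DataFrame({
        "feature_id": values.index,
        "platform_class": platform_class,
        "family": spec.family,
        "comparison_id": spec.comparison_id,
        "basis": spec.basis,
        "n": n_used,
        "p_raw": p,
        "median_fc": fc,
        "direction": direction,
        "flags": flags,
    })


def _apply_fdr(results: pd.DataFrame, scope: str) -> pd.DataFrame:
    """Attach q_fdr within FDR families. Untestable rows (p = NaN) are
    excluded from their family and keep q = NaN."""
    results = results.copy()
    results["q_fdr"] = np.nan
    group_cols = ["platform_class", "family"]
    if scope == "per_comparison":
        group_cols.append("comparison_id")
    elif scope != "pooled":
        raise ValueError(f"unknown FDR scope {scope!r}")
    # pre-test families are always corrected separately per pre-test
    pre = results["family"] == "pretest"
    for _, idx in results[pre].groupby(["platform_class", "comparison_id"]).groups.items():
        ok = idx[results.loc[idx, "p_raw"].notna().to_numpy()]
        if len(ok):
            results.loc[ok, "q_fdr"] = bh_fdr(results.loc[ok, "p_raw"].to_numpy())
    for _, idx in results[~pre].groupby(group_cols).groups.items():
        ok = idx[results.loc[idx, "p_raw"].notna().to_numpy()]
        if len(ok):
            results.loc[ok, "q_fdr"] = bh_fdr(results.loc[ok, "p_raw"].to_numpy())
    return results


def _excretion_values(excretion: pd.DataFrame, sdf: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pivot long excretion records into a feature x pseudo-sample matrix
    with a matching pseudo-sample frame (one column per subject/trial/phase)."""
    exc = excretion.copy()
    exc["sample_id"] = (exc["subject_id"].astype(str) + "|" + exc["trial"].astype(str)
                       + "|" + exc["phase"].astype(str))
    wide = exc.pivot(index="feature_id", columns="sample_id", values="amount")
    pseudo = exc[["sample_id", "subject_id", "trial", "phase"]].drop_duplicates()
    pseudo = pseudo.rename(columns={"phase": "timepoint"})
    pseudo["visit"] = None
    pseudo["is_qc"] = False
    return wide, pseudo.set_index("sample_id", drop=False)


def run_pretests(
    targeted: MeasurementMatrix | None,
    untargeted: MeasurementMatrix | None,
    samples: Sequence[SampleRecord] | pd.DataFrame,
    *,
    paired_targeted: bool = True,
    paired_untargeted: bool = False,
    eligible_untargeted: Sequence[str] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Run the four baseline/carry-over pre-tests per platform class.

    Outcomes are advisory: any feature with q < alpha in a pre-test is
    listed in the ``pretest_warning`` flag column, and the pipeline
    proceeds regardless.
    """
    sdf = samples if isinstance(samples, pd.DataFrame) else samples_frame(samples)
    pieces = []
    if targeted is not None:
        for spec in pretest_scheme(paired_targeted, targeted.basis):
            pieces.append(_run_one_comparison(targeted.values, sdf, spec, "targeted"))
    if untargeted is not None:
        vals = untargeted.values
        if eligible_untargeted is not None:
            vals = vals.loc[[f for f in vals.index if f in set(eligible_untargeted)]]
        for spec in pretest_scheme(paired_untargeted, untargeted.basis):
            pieces.append(_run_one_comparison(vals, sdf, spec, "untargeted"))
    if not pieces:
        raise ValueError("no matrices supplied to run_pretests")
    results = _apply_fdr(pd.concat(pieces, ignore_index=True), scope="per_comparison")
    warn = (results["q_fdr"] < alpha).fillna(False)
    f = results.loc[warn, "flags"]
    results.loc[warn, "flags"] = np.where(f == "", "pretest_warning",
                                          f + ";pretest_warning")
    return results


def run_main_comparisons(
    targeted: MeasurementMatrix | None,
    untargeted: MeasurementMatrix | None,
    excretion: pd.DataFrame | None,
    samples: Sequence[SampleRecord] | pd.DataFrame,
    *,
    paired_targeted: bool = True,
    paired_untargeted: bool = False,
    eligible_untargeted: Sequence[str] | None = None,
    fdr_scope: str = "pooled",
) -> pd.DataFrame:
    """Run the main within-/between-group comparison scheme.

    Targeted metabolites are tested on the osmolality-normalized basis
    (within and between), plus between-trial comparisons of absolute
    excretion per collection phase and cumulative excretion when
    ``excretion`` records are supplied. Untargeted features (restricted to
    ``eligible_untargeted`` when given) are tested on the drift-corrected
    basis, unpaired by default. FDR families pool all within-group
    p-values and, separately, all between-group p-values per platform
    class (``fdr_scope='per_comparison'`` corrects each comparison alone).
    """
    sdf = samples if isinstance(samples, pd.DataFrame) else samples_frame(samples)
    pieces = []
    if targeted is not None:
        if targeted.basis != "osmolality_normalized":
            raise ValueError(
                f"targeted matrix must be on basis 'osmolality_normalized', "
                f"got {targeted.basis!r}")
        specs = main_comparison_scheme(paired_targeted, targeted.basis,
                                       include_excretion=excretion is not None)
        exc_vals = exc_sdf = None
        if excretion is not None:
            exc_vals, exc_sdf = _excretion_values(excretion, sdf)
        for spec in specs:
            if spec.basis in ("absolute_excretion", "cumulative_excretion"):
                pieces.append(_run_one_comparison(exc_vals, exc_sdf, spec, "targeted"))
            else:
                pieces.append(_run_one_comparison(targeted.values, sdf, spec, "targeted"))
    if untargeted is not None:
        if untargeted.basis not in ("drift_corrected", "raw"):
            raise ValueError(
                f"untargeted matrix must be drift-corrected (or raw), "
                f"got {untargeted.basis!r}")
        vals = untargeted.values
        if eligible_untargeted is not None:
            keep = [f for f in vals.index if f in set(eligible_untargeted)]
            vals = vals.loc[keep]
        study_cols = [s for s in vals.columns if not sdf.loc[s, "is_qc"]]
        vals = vals[study_cols]
        for spec in main_comparison_scheme(paired_untargeted, untargeted.basis):
            pieces.append(_run_one_comparison(vals, sdf, spec, "untargeted"))
    if not pieces:
        raise ValueError("no matrices supplied to run_main_comparisons")
    return _apply_fdr(pd.concat(pieces, ignore_index=True), scope=fdr_scope)
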