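"""Summary artifacts: z-scored median heatmap matrix, figures, manifest.

The heatmap matrix holds, for every relevant feature, the median level in
each of the ten (trial, timepoint) subgroups, z-transformed across the
row so temporal shape is comparable between metabolites of very
different abundance. Rows are grouped by major metabolic pathway
(pathways ordered by how many relevant features they contain) and sorted
within a group by decreasing U01(CVE)/U00(CVE) median fold change, so
the strongest vigorous-exercise responders lead each block.
"""

from __future__ import annotations

import hashlib
import json
import os
from datetime import datetime, timezone
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .feature_filter import SUBGROUPS, subgroup_label
from .io_tables import MeasurementMatrix, SampleRecord, samples_frame

__all__ = [
    "zscore_median_matrix",
    "build_manifest",
    "render_reports",
]

#: column order of the heatmap matrix: CME U00..U04 then CVE U00..U04
SUBGROUP_ORDER = [subgroup_label(t, u) for t, u in SUBGROUPS]


def _subgroup_medians(
    values: pd.DataFrame, sdf: pd.DataFrame
) -> pd.DataFrame:
    """Median per (feature, subgroup) over non-QC samples, detected values
    only (no imputation in display)."""
    out = {}
    study = sdf[~sdf["is_qc"]]
    for trial, tp in SUBGROUPS:
        cols = [c for c in study.loc[(study["trial"] == trial)
                                     & (study["timepoint"] == tp), "sample_id"]
                if c in values.columns]
        out[subgroup_label(trial, tp)] = values[cols].median(axis=1, skipna=True)
    return pd.DataFrame(out)[SUBGROUP_ORDER]


def _zscore_rows(medians: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Row-wise z-transform over non-missing subgroup medians (population
    SD; a constant row becomes all zeros). Rows with fewer than 2
    non-missing medians are flagged and left untransformed."""
    z = medians.copy()
    flags = pd.Series("", index=medians.index)
    for feature, row in medians.iterrows():
        vals = row.to_numpy(dtype=float)
        ok = ~np.isnan(vals)
        if ok.sum() < 2:
            flags[feature] = "not_transformed"
            continue
        mean = vals[ok].mean()
        sd = vals[ok].std()  # population SD (ddof=0)
        z.loc[feature] = 0.0 if sd == 0 else (vals - mean) / sd
        z.loc[feature, ~ok] = np.nan
    return z, flags


def zscore_median_matrix(
    targeted: MeasurementMatrix | None,
    untargeted: MeasurementMatrix | None,
    samples: Sequence[SampleRecord] | pd.DataFrame,
    calls: pd.DataFrame,
    feature_meta: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Heatmap matrix of z-transformed subgroup medians for all relevant
    features (any relevance label true).

    Targeted features are read from the normalized targeted matrix,
    untargeted features from the drift-corrected matrix. Returns a
    DataFrame indexed by feature_id with a ``major_pathway`` column, the
    ten subgroup z-columns (CME U00..U04 then CVE U00..U04) and a
    ``flags`` column; an empty call set yields an empty frame with the
    same columns.
    """
    sdf = samples if isinstance(samples, pd.DataFrame) else samples_frame(samples)
    label_cols = ["exercise_responsive_CME", "exercise_responsive_CVE",
                  "intensity_dependent"]
    columns = ["major_pathway"] + SUBGROUP_ORDER + ["flags"]
    if len(calls) == 0:
        return pd.DataFrame(columns=columns)
    relevant = calls[calls[label_cols].any(axis=1)]
    if len(relevant) == 0:
        return pd.DataFrame(columns=columns)
    pieces = []
    for platform_class, matrix in (("targeted", targeted), ("untargeted", untargeted)):
        if matrix is None:
            continue
        ids = [f for f in relevant.loc[relevant["platform_class"] == platform_class,
                                       "feature_id"] if f in matrix.values.index]
        if ids:
            pieces.append(_subgroup_medians(matrix.values.loc[ids], sdf))
    if not pieces:
        return pd.DataFrame(columns=columns)
    medians = pd.concat(pieces)
    z, flags = _zscore_rows(medians)

    pathways = pd.Series("unclassified", index=z.index)
    if feature_meta is not None:
        lookup = feature_meta.set_index("feature_id")["major_pathway"]
        pathways = pathways.index.to_series().map(lookup).fillna("unclassified")
    # sort key 1: pathways by descending relevant-feature count, then name
    group_size = pathways.value_counts()
    path_rank = {p: (-group_size[p], p) for p in group_size.index}
    # sort key 2: decreasing U01(CVE)/U00(CVE) median fold change
    with np.errstate(divide="ignore", invalid="ignore"):
        cve_fc = medians["CVE:U01"] / medians["CVE:U00"]
    order = sorted(
        z.index,
        key=lambda f: (path_rank[pathways[f]],
                       -(cve_fc[f] if np.isfinite(cve_fc[f]) else -np.inf)))
    out = z.loc[order].copy()
    out.insert(0, "major_pathway", pathways.loc[order])
    out["flags"] = flags.loc[order]
    out.index.name = "feature_id"
    return out


def build_manifest(
    config_dict: Mapping, seed: int | None, counts: Mapping[str, int]
) -> dict:
    """Machine-readable run manifest: canonical config hash, seed, library
    versions and per-stage feature counts. Two runs with the same config
    and seed differ only in ``generated_at``."""
    import matplotlib
    import scipy
    import statsmodels

    from . import __version__

    canonical = json.dumps(config_dict, sort_keys=True, default=str)
    return {
        "config": json.loads(canonical),
        "config_hash": hashlib.sha256(canonical.encode()).hexdigest(),
        "seed": seed,
        "counts": dict(counts),
        "versions": {
            "uromet": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
            "statsmodels": statsmodels.__version__,
            "matplotlib": matplotlib.__version__,
        },
        "generated_at": datetime.now(timezone.utc).isoformat(),
    }


def _render_heatmap(heatmap: pd.DataFrame, path: str) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = heatmap[SUBGROUP_ORDER].to_numpy(dtype=float) if len(heatmap) else \
        np.empty((0, len(SUBGROUP_ORDER)))
    n_rows = max(1, data.shape[0])
    fig, ax = plt.subplots(figsize=(6, max(2.0, 0.18 * n_rows)))
    if data.size:
        masked = np.ma.masked_invalid(data)
        cmap = plt.get_cmap("RdBu_r").copy()
        cmap.set_bad("0.85")
        im = ax.imshow(masked, aspect="auto", cmap=cmap, vmin=-2.5, vmax=2.5)
        fig.colorbar(im, ax=ax, label="z-scored subgroup median")
        ax.set_yticks(range(data.shape[0]))
        ax.set_yticklabels(heatmap.index, fontsize=4)
    else:
        ax.text(0.5, 0.5, "no relevant features", ha="center", va="center")
    ax.set_xticks(range(len(SUBGROUP_ORDER)))
    ax.set_xticklabels(SUBGROUP_ORDER, rotation=90, fontsize=6)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _render_venn(venn_counts: pd.DataFrame, path: str) -> None:
    """Three-circle Venn with region counts (drawn directly; the counts
    come from classify.summarize_venn)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    c = dict(zip(venn_counts["region"], venn_counts["count"]))
    fig, ax = plt.subplots(figsize=(5, 5))
    centers = {"CME": (-0.35, 0.25), "CVE": (0.35, 0.25), "intensity": (0.0, -0.4)}
    colors = {"CME": "tab:blue", "CVE": "tab:orange", "intensity": "tab:green"}
    for name, (x, y) in centers.items():
        ax.add_patch(Circle((x, y), 0.62, alpha=0.3, color=colors[name]))
    labels = {
        (-0.55, 0.45): c.get("CME_only", 0),
        (0.55, 0.45): c.get("CVE_only", 0),
        (0.0, -0.75): c.get("intensity_only", 0),
        (0.0, 0.45): c.get("CME_CVE", 0),
        (-0.35, -0.15): c.get("CME_intensity", 0),
        (0.35, -0.15): c.get("CVE_intensity", 0),
        (0.0, 0.05): c.get("all_three", 0),
    }
    for (x, y), n in labels.items():
        ax.text(x, y, str(n), ha="center", va="center", fontsize=12)
    ax.text(-0.75, 0.95, f"CME-responsive ({c.get('CME_responsive_total', 0)})")
    ax.text(0.25, 0.95, f"CVE-responsive ({c.get('CVE_responsive_total', 0)})")
    ax.text(-0.35, -1.15,
            f"intensity-dependent ({c.get('intensity_dependent_total', 0)})")
    ax.set_xlim(-1.3, 1.3)
    ax.set_ylim(-1.3, 1.3)
    ax.set_aspect("equal")
    ax.axis("off")
    fig.savefig(path, dpi=150)
    plt.close(fig)


def _render_candidate_plots(
    triage: pd.DataFrame,
    untargeted: MeasurementMatrix,
    samples,
    out_dir: str,
) -> list[str]:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sdf = samples if isinstance(samples, pd.DataFrame) else samples_frame(samples)
    study = sdf[~sdf["is_qc"]]
    os.makedirs(out_dir, exist_ok=True)
    paths = []
    candidates = triage.loc[triage["route"].isin(["heuristic_candidate", "heuristic"]),
                            "feature_id"]
    for feature in candidates:
        if feature not in untargeted.values.index:
            continue
        fig, ax = plt.subplots(figsize=(7, 3))
        data, labels = [], []
        for trial, tp in SUBGROUPS:
            cols = [c for c in study.loc[(study["trial"] == trial)
                                         & (study["timepoint"] == tp), "sample_id"]
                    if c in untargeted.values.columns]
            vals = untargeted.values.loc[feature, cols].dropna().to_numpy()
            data.append(vals)
            labels.append(subgroup_label(trial, tp))
        ax.boxplot([d if len(d) else [np.nan] for d in data], tick_labels=labels)
        medians = [np.median(d) if len(d) else np.nan for d in data]
        ax.plot(range(1, len(medians) + 1), medians, "o-", color="tab:red", ms=3)
        ax.set_title(f"{feature} (heuristic candidate)", fontsize=9)
        ax.tick_params(axis="x", rotation=90, labelsize=6)
        fig.tight_layout()
        path = os.path.join(out_dir, f"{feature}.png")
        fig.savefig(path, dpi=120)
        plt.close(fig)
        paths.append(path)
    return paths


def render_reports(
    out_dir: str | os.PathLike,
    manifest: Mapping,
    heatmap: pd.DataFrame | None = None,
    venn_counts: pd.DataFrame | None = None,
    triage: pd.DataFrame | None = None,
    untargeted: MeasurementMatrix | None = None,
    samples=None,
) -> dict[str, object]:
    """Write the run manifest and (best-effort) the figures: heatmap,
    Venn diagram and per-candidate review plots. Rendering failures are
    recorded in the returned dict, never raised."""
    out_dir = str(out_dir)
    os.makedirs(out_dir, exist_ok=True)
    written: dict[str, object] = {}
    manifest_path = os.path.join(out_dir, "manifest.json")
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    written["manifest"] = manifest_path
    jobs = []
    if heatmap is not None:
        jobs.append(("heatmap", _render_heatmap, (heatmap,
                                                  os.path.join(out_dir, "heatmap.png"))))
    if venn_counts is not None:
        jobs.append(("venn", _render_venn, (venn_counts,
                                            os.path.join(out_dir, "venn.png"))))
    if triage is not None and untargeted is not None and samples is not None:
        jobs.append(("candidates", _render_candidate_plots,
                     (triage, untargeted, samples,
                      os.path.join(out_dir, "candidates"))))
    for name, fn, args in jobs:
        try:
            result = fn(*args)
            written[name] = result if result is not None else args[-1]
        except Exception as exc:  # pragma: no cover - rendering is best-effort
            written[name] = f"render failed: {exc}"
    return written
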