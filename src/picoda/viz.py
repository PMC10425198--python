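"""Data layers and figure rendering for the three canonical plots.

Every visual quantity (group means, SEMs, PC coordinates, z-scores) is
computed first into a *layer* object that serializes to TSV, and only then
drawn; tests and downstream tooling assert on layers, never on pixels.
Figures are rendered with matplotlib to any of SVG/PDF/PNG.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats

from .daa import DAResult, tss_normalize
from .io import DataError, FeatureTable, SampleMetadata

logger = logging.getLogger("picoda")

__all__ = [
    "ErrorbarLayer",
    "PcaLayer",
    "HeatmapLayer",
    "pathway_errorbar",
    "pathway_pca",
    "pathway_heatmap",
]

MAX_ERRORBAR_FEATURES = 30


@dataclass
class ErrorbarLayer:
    """Per-(feature, group) relative-abundance means and SEMs, with the DA
    annotation columns (log2 effect and adjusted p) and a display order."""

    stats: pd.DataFrame  # feature, group, mean_rel_abund, sem
    annotation: pd.DataFrame  # feature, effect, p_adjust (display order)

    def to_tsv(self, path) -> None:
        merged = self.stats.merge(self.annotation, on="feature")
        merged.to_csv(path, sep="\t", index=False)


@dataclass
class PcaLayer:
    """Sample scores on the leading principal components plus the variance
    fraction each component explains."""

    scores: pd.DataFrame  # sample, group, PC1..PCk
    variance_fraction: np.ndarray

    def to_tsv(self, path) -> None:
        out = self.scores.copy()
        pcs = [c for c in out.columns if c.startswith("PC")]
        header = {
            pc: f"{pc} ({100 * vf:.1f}%)"
            for pc, vf in zip(pcs, self.variance_fraction)
        }
        out.rename(columns=header).to_csv(path, sep="\t", index=False)


@dataclass
class HeatmapLayer:
    """Row-wise z-score matrix with group-then-sample column ordering."""

    zscores: pd.DataFrame  # features x ordered samples
    groups: pd.Series  # group label per ordered sample

    def to_tsv(self, path) -> None:
        self.zscores.to_csv(path, sep="\t", index_label="function")


def _save(fig, figure_path: Optional[str | Path]) -> None:
    if figure_path is None:
        plt.close(fig)
        return
    fig.savefig(figure_path, dpi=300, bbox_inches="tight")
    plt.close(fig)


def pathway_errorbar(
    table: FeatureTable,
    meta: SampleMetadata,
    results: Sequence[DAResult],
    threshold: float = 0.05,
    order_by: str = "p",
    select: Optional[set[str]] = None,
    figure_path: Optional[str | Path] = None,
    labels: Optional[dict[str, str]] = None,
) -> ErrorbarLayer:
    """Group mean +/- SEM of relative abundance for significant features.

    Features with adjusted p below ``threshold`` (optionally restricted to
    ``select``) are shown, at most 30; ordering is by adjusted p, feature
    name, or group of maximal abundance, with ties broken by feature ID.
    ``labels`` optionally maps feature IDs to display names.
    """
    by_feature = {r.feature: r for r in results}
    missing = [f for f in by_feature if f not in set(table.feature_ids)]
    if missing:
        raise DataError(f"results contain features absent from the table: {missing[:5]}")
    sig = [r for r in results if r.p_adjust < threshold]
    if select is not None:
        sig = [r for r in sig if r.feature in select]
    if not sig:
        raise DataError(
            f"no features significant at adjusted p < {threshold}; nothing to plot"
        )
    if len(sig) > MAX_ERRORBAR_FEATURES:
        raise DataError(
            f"{len(sig)} significant features exceed the {MAX_ERRORBAR_FEATURES}-"
            f"feature cap; pass `select` to choose a subset"
        )

    rel = tss_normalize(table)
    idx = {f: i for i, f in enumerate(rel.feature_ids)}
    levels = meta.levels
    rows = []
    for r in sig:
        vec = rel.values[idx[r.feature]]
        for lev in levels:
            mask = np.asarray([meta.group[s] == lev for s in meta.sample_ids])
            vals = vec[mask]
            rows.append({
                "feature": r.feature, "group": lev,
                "mean_rel_abund": float(vals.mean()),
                "sem": float(vals.std(ddof=1) / np.sqrt(vals.size))
                if vals.size > 1 else 0.0,
            })
    stats_frame = pd.DataFrame(rows)

    if order_by == "p":
        key = lambda r: (r.p_adjust, r.feature)
    elif order_by == "name":
        key = lambda r: (r.feature,)
    elif order_by == "group":
        group_of = {
            f: stats_frame[stats_frame["feature"] == f]
            .sort_values(["mean_rel_abund", "group"], ascending=[False, True])
            .iloc[0]["group"]
            for f in {r.feature for r in sig}
        }
        key = lambda r: (levels.index(group_of[r.feature]), r.feature)
    else:
        raise DataError(f"unknown order_by {order_by!r}; use p, name or group")
    ordered = sorted(sig, key=key)
    annotation = pd.DataFrame(
        [{"feature": r.feature, "effect": r.effect, "p_adjust": r.p_adjust}
         for r in ordered]
    )
    order = [r.feature for r in ordered]
    stats_frame["feature"] = pd.Categorical(
        stats_frame["feature"], categories=order, ordered=True
    )
    stats_frame = stats_frame.sort_values(["feature", "group"]).reset_index(drop=True)
    stats_frame["feature"] = stats_frame["feature"].astype(str)
    layer = ErrorbarLayer(stats=stats_frame, annotation=annotation)

    if figure_path is not None:
        fig, (ax, ax2) = plt.subplots(
            1, 2, figsize=(9, 0.45 * len(order) + 1.5),
            gridspec_kw={"width_ratios": [3, 1]}, sharey=True,
        )
        ypos = np.arange(len(order))[::-1]
        width = 0.8 / len(levels)
        for gi, lev in enumerate(levels):
            sub = stats_frame[stats_frame["group"] == lev].set_index("feature")
            ax.barh(
                ypos + (gi - (len(levels) - 1) / 2) * width,
                [sub.loc[f, "mean_rel_abund"] for f in order],
                xerr=[sub.loc[f, "sem"] for f in order],
                height=width, label=str(lev), capsize=2,
            )
        ax.set_yticks(ypos)
        ax.set_yticklabels([(labels or {}).get(f, f) for f in order], fontsize=8)
        ax.set_xlabel("mean relative abundance")
        ax.legend(title="group", fontsize=8)
        for y, r in zip(ypos, ordered):
            ax2.text(0.05, y, f"{r.effect:+.2f}", fontsize=8, va="center")
            ax2.text(0.55, y, f"{r.p_adjust:.2e}", fontsize=8, va="center")
        ax2.set_xlim(0, 1)
        ax2.set_ylim(ax.get_ylim())
        ax2.axis("off")
        ax2.set_title("log2FC  /  adj. p", fontsize=8)
        _save(fig, figure_path)
    return layer


def pathway_pca(
    table: FeatureTable,
    meta: SampleMetadata,
    k: int = 2,
    scale: bool = False,
    figure_path: Optional[str | Path] = None,
) -> PcaLayer:
    """PCA of samples on TSS-normalized, feature-centered abundances.

    Relative abundances put every feature on one scale, so features are
    centered but (by default) not variance-scaled before the SVD.  The
    figure shows PC1 vs PC2 colored by group with 95% normal-theory
    ellipses (chi-square, 2 df); axis labels carry the variance
    percentages.
    """
    if table.n_samples < 2 or table.n_features < 2:
        raise DataError("PCA needs >= 2 samples and >= 2 features")
    rel = tss_normalize(table).values
    centered = rel - rel.mean(axis=1, keepdims=True)
    if scale:
        sd = centered.std(axis=1, ddof=1)
        sd[sd == 0] = 1.0
        centered = centered / sd[:, None]
    # samples x features orientation for the decomposition
    U, s, Vt = np.linalg.svd(centered.T, full_matrices=False)
    lam = s**2
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if k > rank:
        raise DataError(f"k={k} exceeds the rank ({rank}) of the centered matrix")
    var_frac = lam / lam.sum()
    scores = U[:, :k] * s[:k]
    frame = pd.DataFrame(
        scores, columns=[f"PC{i + 1}" for i in range(k)]
    )
    frame.insert(0, "sample", table.sample_ids)
    frame.insert(1, "group", [meta.group[s_] for s_ in table.sample_ids])
    layer = PcaLayer(scores=frame, variance_fraction=var_frac[:k])

    if figure_path is not None:
        fig, ax = plt.subplots(figsize=(5, 4.5))
        radius = np.sqrt(stats.chi2.ppf(0.95, df=2))
        for lev in meta.levels:
            sub = frame[frame["group"] == lev]
            pts = ax.scatter(sub["PC1"], sub["PC2"] if k > 1 else 0, label=str(lev), s=25)
            if k > 1 and len(sub) > 2:
                xy = sub[["PC1", "PC2"]].to_numpy()
                cov = np.cov(xy.T)
                mean = xy.mean(axis=0)
                evals, evecs = np.linalg.eigh(cov)
                theta = np.linspace(0, 2 * np.pi, 200)
                circle = np.stack([np.cos(theta), np.sin(theta)])
                ell = (evecs @ (np.sqrt(np.maximum(evals, 0))[:, None] * circle)) * radius
                ax.plot(mean[0] + ell[0], mean[1] + ell[1],
                        color=pts.get_facecolor()[0], lw=1)
        ax.set_xlabel(f"PC1 ({100 * var_frac[0]:.1f}%)")
        if k > 1:
            ax.set_ylabel(f"PC2 ({100 * var_frac[1]:.1f}%)")
        ax.legend(title="group", fontsize=8)
        _save(fig, figure_path)
    return layer


def pathway_heatmap(
    table: FeatureTable,
    meta: SampleMetadata,
    features: Optional[set[str]] = None,
    figure_path: Optional[str | Path] = None,
) -> HeatmapLayer:
    """Row-wise z-score heatmap with columns grouped by metadata.

    Rows are z-scored with the sample standard deviation; constant rows
    become all-zero (warning).  Columns are ordered by group, then sample
    ID.
    """
    if features is not None:
        if not features:
            raise DataError("empty feature selection")
        missing = sorted(features - set(table.feature_ids))
        if missing:
            raise DataError(f"requested features absent from table: {missing[:5]}")
        table = table.select_features(sorted(features))
    order = sorted(
        table.sample_ids, key=lambda s: (str(meta.group[s]), s)
    )
    sub = table.select_samples(order)
    x = sub.values
    mean = x.mean(axis=1, keepdims=True)
    sd = x.std(axis=1, ddof=1)
    const = sd == 0
    if np.any(const):
        logger.warning("%d constant row(s) z-scored to all zeros", int(const.sum()))
    sd_safe = np.where(const, 1.0, sd)
    z = (x - mean) / sd_safe[:, None]
    z[const] = 0.0
    zframe = pd.DataFrame(z, index=sub.feature_ids, columns=order)
    groups = pd.Series([meta.group[s] for s in order], index=order, name="group")
    layer = HeatmapLayer(zscores=zframe, groups=groups)

    if figure_path is not None:
        fig, ax = plt.subplots(
            figsize=(0.35 * len(order) + 2, 0.3 * len(sub.feature_ids) + 1.5)
        )
        im = ax.imshow(z, aspect="auto", cmap="RdBu_r")
        ax.set_xticks(range(len(order)))
        ax.set_xticklabels(order, rotation=90, fontsize=7)
        ax.set_yticks(range(len(sub.feature_ids)))
        ax.set_yticklabels(sub.feature_ids, fontsize=7)
        # group bands along the top
        start = 0
        for lev, block in groups.groupby(groups, sort=False):
            ax.axvline(start - 0.5, color="black", lw=0.5)
            ax.text((start + start + len(block) - 1) / 2, -0.8, str(lev),
                    ha="center", fontsize=8)
            start += len(block)
        fig.colorbar(im, ax=ax, shrink=0.6, label="row z-score")
        _save(fig, figure_path)
    return layer
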