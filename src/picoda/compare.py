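"""Cross-method consensus reports and cross-metagenome comparisons.

``compare_daa_results`` summarizes how the significant-feature sets of
several DA methods overlap (common, unique, pairwise Jaccard).
``compare_metagenome_results`` concatenates feature tables from different
metagenome predictions, runs one DA method with the source as the group
factor, and reports per-sample Spearman correlations between each pair of
sources.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .daa import DAResult, pathway_daa
from .io import DataError, FeatureTable, Namespace, SampleMetadata

logger = logging.getLogger("picoda")

__all__ = [
    "ConsensusReport",
    "MetagenomeComparison",
    "compare_daa_results",
    "spearman",
    "compare_metagenome_results",
]


@dataclass
class ConsensusReport:
    """Overlap structure of significant features across DA methods."""

    threshold: float
    per_method_sig_counts: dict[str, int]
    significant_sets: dict[str, set[str]]
    common_features: set[str]
    unique_features: dict[str, set[str]]
    pairwise_jaccard: dict[tuple[str, str], float]

    def to_frames(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(per-method summary, pairwise Jaccard) frames for TSV export."""
        summary = pd.DataFrame(
            {
                "method": sorted(self.per_method_sig_counts),
                "n_significant": [
                    self.per_method_sig_counts[m]
                    for m in sorted(self.per_method_sig_counts)
                ],
                "unique_features": [
                    ";".join(sorted(self.unique_features[m]))
                    for m in sorted(self.per_method_sig_counts)
                ],
            }
        )
        pairs = pd.DataFrame(
            [
                {"method_a": a, "method_b": b, "jaccard": j}
                for (a, b), j in sorted(self.pairwise_jaccard.items())
            ]
        )
        return summary, pairs


def compare_daa_results(
    results_by_method: dict[str, Sequence[DAResult]],
    threshold: float = 0.05,
) -> ConsensusReport:
    """Compare significant-feature sets (adjusted p < threshold) across methods.

    Jaccard similarity of two empty sets is 1 by convention (the methods
    agree that nothing is significant).
    """
    if len(results_by_method) < 2:
        raise DataError("need results from >= 2 methods to compare")
    universes = {
        m: frozenset(r.feature for r in res)
        for m, res in results_by_method.items()
    }
    if len(set(universes.values())) != 1:
        raise DataError("methods were run on different feature universes")
    contrasts = {
        m: frozenset((r.group1, r.group2) for r in res)
        for m, res in results_by_method.items()
    }
    if len(set(contrasts.values())) != 1:
        raise DataError("methods were run on different group contrasts")

    sig = {
        m: {r.feature for r in res if r.p_adjust < threshold}
        for m, res in results_by_method.items()
    }
    methods = sorted(sig)
    common = set.intersection(*(sig[m] for m in methods))
    unique = {
        m: sig[m] - set().union(*(sig[o] for o in methods if o != m))
        for m in methods
    }
    jaccard: dict[tuple[str, str], float] = {}
    for a, b in itertools.combinations(methods, 2):
        union = sig[a] | sig[b]
        jaccard[(a, b)] = (
            1.0 if not union else len(sig[a] & sig[b]) / len(union)
        )
    return ConsensusReport(
        threshold=threshold,
        per_method_sig_counts={m: len(sig[m]) for m in methods},
        significant_sets=sig,
        common_features=common,
        unique_features=unique,
        pairwise_jaccard=jaccard,
    )


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with a two-sided t-approximation p-value.

    Ties receive average ranks; ``|rho| = 1`` returns ``p = 0`` by
    convention; a constant vector has no rank variance and is an error.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise DataError("spearman needs two equal-length vectors with n >= 3")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise DataError("zero rank variance: constant input vector")
    rho, p = stats.spearmanr(x, y)
    if not np.isfinite(rho):
        raise DataError("zero rank variance: constant input vector")
    if abs(rho) >= 1.0 - 1e-15:
        return float(np.sign(rho)), 0.0
    return float(rho), float(p)


@dataclass
class MetagenomeComparison:
    """DA across metagenome sources plus pairwise per-sample correlations."""

    source_names: list[str]
    da_results: list[DAResult]
    pairwise_rho: dict[tuple[str, str], dict] = field(default_factory=dict)
    # each value: {"per_sample_rho": {...}, "p_values": {...}, "mean_rho": float}
    # or {"missing": True} when the pair shares no sample names

    def pairwise_frame(self) -> pd.DataFrame:
        rows = []
        for (a, b), entry in sorted(self.pairwise_rho.items()):
            if entry.get("missing"):
                rows.append({"source_a": a, "source_b": b, "sample": "",
                             "rho": np.nan, "p_value": np.nan})
                continue
            for s in sorted(entry["per_sample_rho"]):
                rows.append({
                    "source_a": a, "source_b": b, "sample": s,
                    "rho": entry["per_sample_rho"][s],
                    "p_value": entry["p_values"][s],
                })
        return pd.DataFrame(rows)


def compare_metagenome_results(
    tables: dict[str, FeatureTable],
    daa_method: str = "linda_like",
    adjust: str = "BH",
    reference: Optional[str] = None,
    seed: int = 42,
) -> MetagenomeComparison:
    """Compare metagenome predictions from different sources.

    All tables are restricted to their shared feature set and concatenated
    with the source name as the group factor (sample IDs are suffixed with
    the source to stay unique); one DA run contrasts the sources.  For
    each source pair, samples with the same original name are correlated
    (Spearman, across shared features) and averaged into ``mean_rho``.
    """
    if len(tables) < 2:
        raise DataError("need >= 2 metagenome tables to compare")
    names = sorted(tables)
    shared = set(tables[names[0]].feature_ids)
    for nm in names[1:]:
        shared &= set(tables[nm].feature_ids)
    if not shared:
        raise DataError("metagenome tables share no features")
    features = sorted(shared)

    blocks, sample_ids, groups = [], [], []
    restricted: dict[str, FeatureTable] = {}
    for nm in names:
        t = tables[nm].select_features(features)
        restricted[nm] = t
        blocks.append(t.values)
        sample_ids.extend(f"{s}__{nm}" for s in t.sample_ids)
        groups.extend([nm] * t.n_samples)
    concat = FeatureTable(
        feature_ids=features,
        sample_ids=sample_ids,
        values=np.concatenate(blocks, axis=1),
        namespace=tables[names[0]].namespace,
    )
    ref = reference if reference is not None else names[0]
    meta = SampleMetadata(
        sample_ids=sample_ids,
        group=pd.Series(groups, index=sample_ids),
        reference_group=ref,
    )
    da = pathway_daa(concat, meta, method=daa_method, adjust=adjust, seed=seed)

    pairwise: dict[tuple[str, str], dict] = {}
    for a, b in itertools.combinations(names, 2):
        ta, tb = restricted[a], restricted[b]
        shared_samples = sorted(set(ta.sample_ids) & set(tb.sample_ids))
        if not shared_samples:
            logger.warning("sources %s and %s share no sample names", a, b)
            pairwise[(a, b)] = {"missing": True}
            continue
        rhos, ps = {}, {}
        for s in shared_samples:
            va = ta.values[:, ta.sample_ids.index(s)]
            vb = tb.values[:, tb.sample_ids.index(s)]
            rho, p = spearman(va, vb)
            rhos[s], ps[s] = rho, p
        pairwise[(a, b)] = {
            "per_sample_rho": rhos,
            "p_values": ps,
            "mean_rho": float(np.mean(list(rhos.values()))),
        }
    return MetagenomeComparison(
        source_names=names, da_results=da, pairwise_rho=pairwise
    )
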