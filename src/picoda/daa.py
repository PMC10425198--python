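"""Differential-abundance engine for predicted functional profiles.

A registry of natively implemented DA statistics sharing one input/output
contract.  Each method takes an aligned :class:`~picoda.io.FeatureTable`
and :class:`~picoda.io.SampleMetadata` and returns one
:class:`DAResult` per feature (per contrast).  The methods are documented,
simplified analogues of the tools commonly wrapped in microbiome pipelines:

``welch_t``
    Welch's t-test on CLR-transformed abundances (compositional baseline).
``kruskal_wallis``
    Rank-based omnibus H test on relative abundances.
``aldex2_like``
    Dirichlet Monte-Carlo instances + CLR + per-instance test, results
    averaged over instances.
``linda_like``
    CLR linear model with compositional-bias correction by mode centering.
``limma_like``
    Empirical-Bayes moderated t on log2-CPM with median-of-ratios
    effective library sizes.
``css_like``
    Cumulative-sum scaling normalization, then Welch on the log scale.
``maaslin2_like``
    TSS -> log transform with half-minimum pseudocount -> per-feature
    linear model; covariates enter additively.
``lefse_like``
    Kruskal-Wallis screen followed by a univariate log10 effect score.

Effects are reported on the log2 scale throughout (per-method definitions
in the docstrings); p-values are two-sided and corrected for multiple
testing with BH by default.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .io import DataError, FeatureTable, Namespace, SampleMetadata

logger = logging.getLogger("picoda")

__all__ = [
    "DAResult",
    "tss_normalize",
    "clr_transform",
    "adjust_pvalues",
    "welch_t_test",
    "kruskal_wallis_test",
    "pathway_daa",
    "results_to_frame",
    "write_da_results",
    "METHODS",
    "ADJUST_METHODS",
]

ADJUST_METHODS = ("BH", "bonferroni", "holm", "BY", "none")

# DESeq2- and edgeR-style negative-binomial GLMs are recognized names with
# reserved registry slots but intentionally not implemented.
RESERVED_METHODS = ("deseq2_like", "edger_like")

_LN2 = math.log(2.0)


@dataclass
class DAResult:
    """Per-feature differential-abundance record for one group contrast."""

    feature: str
    method: str
    group1: str  # reference level
    group2: str
    effect: float  # log2-scale, method-specific (see method docstrings)
    p_value: float
    p_adjust: float
    adjust_method: str = "BH"


# ---------------------------------------------------------------------------
# transforms & multiple testing
# ---------------------------------------------------------------------------

def tss_normalize(table: FeatureTable) -> FeatureTable:
    """Total-sum scaling: divide each sample column by its sum."""
    colsum = table.values.sum(axis=0)
    bad = np.where(colsum <= 0)[0]
    if bad.size:
        raise DataError(
            f"all-zero sample column(s): {[table.sample_ids[i] for i in bad]}"
        )
    return replace(table, values=table.values / colsum)


def clr_transform(
    table_or_values: FeatureTable | np.ndarray, pseudocount: float = 0.5
) -> np.ndarray:
    """Centered log-ratio transform, columns (samples) centered to zero.

    ``y_is = ln(x_is + c) - mean_j ln(x_js + c)`` with pseudocount ``c``.
    With ``pseudocount=0`` the data must be strictly positive.
    """
    x = (
        table_or_values.values
        if isinstance(table_or_values, FeatureTable)
        else np.asarray(table_or_values, dtype=float)
    )
    if pseudocount < 0:
        raise DataError("pseudocount must be non-negative")
    if pseudocount == 0 and np.any(x <= 0):
        raise DataError("pseudocount 0 requires strictly positive data")
    logx = np.log(x + pseudocount)
    return logx - logx.mean(axis=0, keepdims=True)


def adjust_pvalues(p: Sequence[float], method: str = "BH") -> np.ndarray:
    """Multiple-testing correction (BH, bonferroni, holm, BY or none)."""
    p = np.asarray(p, dtype=float)
    if p.size and (np.nanmin(p) < 0 or np.nanmax(p) > 1):
        raise DataError("p-values must lie in [0, 1]")
    if method == "none":
        return p.copy()
    sm_name = {"BH": "fdr_bh", "bonferroni": "bonferroni", "holm": "holm",
               "BY": "fdr_by"}.get(method)
    if sm_name is None:
        raise DataError(f"unknown adjustment method {method!r}; use one of {ADJUST_METHODS}")
    if p.size == 0:
        return p.copy()
    return multipletests(p, method=sm_name)[1]


# ---------------------------------------------------------------------------
# elemental tests (scalar API + row-wise vectorized kernels)
# ---------------------------------------------------------------------------

def welch_t_test(x: Sequence[float], y: Sequence[float]) -> tuple[float, float, float]:
    """Welch's unequal-variance t-test, two-sided.

    Returns ``(t, satterthwaite_df, p)``.  Degenerate inputs follow the
    conventions: both groups constant and equal -> (0, df, 1); both
    constant and unequal -> p = 0 with a warning.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise DataError("welch_t_test needs >= 2 observations per group")
    # the row-wise kernel is oriented second-minus-first; the scalar API
    # follows the usual x-vs-y sign convention
    t, df, p = _welch_rowwise(y[None, :], x[None, :])
    return float(t[0]), float(df[0]), float(p[0])


def _welch_rowwise(
    X: np.ndarray, Y: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Vectorized Welch t over rows of two (features x samples) blocks."""
    n1, n2 = X.shape[1], Y.shape[1]
    m1, m2 = X.mean(axis=1), Y.mean(axis=1)
    v1 = X.var(axis=1, ddof=1)
    v2 = Y.var(axis=1, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        se2 = v1 / n1 + v2 / n2
        t = (m2 - m1) / np.sqrt(se2)
        df = se2**2 / (v1**2 / (n1**2 * (n1 - 1)) + v2**2 / (n2**2 * (n2 - 1)))
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_se = se2 == 0
    if np.any(zero_se):
        equal = zero_se & (m1 == m2)
        unequal = zero_se & (m1 != m2)
        t[equal], p[equal], df[equal] = 0.0, 1.0, n1 + n2 - 2
        if np.any(unequal):
            logger.warning(
                "%d feature(s) constant within both groups but unequal between; "
                "p set to 0 by convention", int(unequal.sum()),
            )
            t[unequal] = np.sign(m2[unequal] - m1[unequal]) * np.inf
            p[unequal], df[unequal] = 0.0, n1 + n2 - 2
    return t, df, p


def kruskal_wallis_test(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H test with tie correction, p from chi-square.

    All-identical input returns ``(0, 1)`` by convention.
    """
    if len(groups) < 2:
        raise DataError("kruskal_wallis_test needs >= 2 groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    pooled = np.concatenate(arrays)
    if pooled.size < 3:
        raise DataError("kruskal_wallis_test needs total n >= 3")
    if np.all(pooled == pooled[0]):
        return 0.0, 1.0
    labels = np.concatenate(
        [np.full(a.size, i) for i, a in enumerate(arrays)]
    )
    H, p = _kruskal_rowwise(pooled[None, :], labels, len(arrays))
    return float(H[0]), float(p[0])


def _kruskal_rowwise(
    values: np.ndarray, labels: np.ndarray, k: int
) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized tie-corrected Kruskal-Wallis H over rows."""
    n = values.shape[1]
    ranks = stats.rankdata(values, axis=1)
    H = np.zeros(values.shape[0])
    for g in range(k):
        mask = labels == g
        ng = int(mask.sum())
        H += ranks[:, mask].sum(axis=1) ** 2 / ng
    H = 12.0 / (n * (n + 1)) * H - 3.0 * (n + 1)
    # tie correction per row
    tie_term = np.zeros(values.shape[0])
    for i in range(values.shape[0]):
        _, counts = np.unique(values[i], return_counts=True)
        tie_term[i] = np.sum(counts**3 - counts)
    correction = 1.0 - tie_term / (n**3 - n)
    with np.errstate(divide="ignore", invalid="ignore"):
        H = H / correction
    p = stats.chi2.sf(H, k - 1)
    degenerate = correction <= 0  # all values identical in the row
    H[degenerate], p[degenerate] = 0.0, 1.0
    return H, p


def _wilcoxon_rowwise(
    X: np.ndarray, Y: np.ndarray
) -> np.ndarray:
    """Two-sided rank-sum p-values (normal approximation, tie-corrected)."""
    n1, n2 = X.shape[1], Y.shape[1]
    n = n1 + n2
    pooled = np.concatenate([X, Y], axis=1)
    ranks = stats.rankdata(pooled, axis=1)
    W = ranks[:, n1:].sum(axis=1)
    mu = n2 * (n + 1) / 2.0
    tie_term = np.array(
        [np.sum(c**3 - c) for c in
         (np.unique(row, return_counts=True)[1] for row in pooled)]
    )
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (W - mu) / np.sqrt(var)
        p = 2.0 * stats.norm.sf(np.abs(z))
    p[var <= 0] = 1.0
    return p


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _two_group_masks(meta: SampleMetadata) -> tuple[np.ndarray, np.ndarray, str, str]:
    levels = meta.levels
    if len(levels) != 2:
        raise DataError(
            f"this method handles exactly 2 groups, got {len(levels)}: {levels}"
        )
    g = np.asarray([meta.group[s] for s in meta.sample_ids])
    return g == levels[0], g == levels[1], levels[0], levels[1]


def _results(
    table: FeatureTable, method: str, g1: str, g2: str,
    effect: np.ndarray, p: np.ndarray, adjust: str,
) -> list[DAResult]:
    padj = adjust_pvalues(p, adjust)
    return [
        DAResult(feature=f, method=method, group1=g1, group2=g2,
                 effect=float(e), p_value=float(pv), p_adjust=float(pa),
                 adjust_method=adjust)
        for f, e, pv, pa in zip(table.feature_ids, effect, p, padj)
    ]


def _half_min_positive(x: np.ndarray, axis=None) -> float | np.ndarray:
    pos = np.where(x > 0, x, np.inf)
    return pos.min(axis=axis) / 2.0


# ---------------------------------------------------------------------------
# registry methods
# ---------------------------------------------------------------------------

def welch_t(
    table: FeatureTable, meta: SampleMetadata, adjust: str = "BH",
    pseudocount: float = 0.5, **_,
) -> list[DAResult]:
    """Welch's t-test per feature on CLR-transformed abundances.

    The CLR backbone makes the baseline test robust to the compositional
    renormalization that a change in a few dominant features imposes on
    all others.  Effect = difference of group mean CLR values on the log2
    scale.
    """
    m1, m2, g1, g2 = _two_group_masks(meta)
    clr = clr_transform(table, pseudocount=pseudocount)
    t, df, p = _welch_rowwise(clr[:, m1], clr[:, m2])
    effect = (clr[:, m2].mean(axis=1) - clr[:, m1].mean(axis=1)) / _LN2
    return _results(table, "welch_t", g1, g2, effect, p, adjust)


def kruskal_wallis(
    table: FeatureTable, meta: SampleMetadata, adjust: str = "BH", **_,
) -> list[DAResult]:
    """Omnibus Kruskal-Wallis H test on relative abundances.

    For two groups the effect is the log2 ratio of group mean relative
    abundances (half-minimum pseudocount); for more groups the contrast is
    omnibus and the effect is reported as 0.
    """
    rel = tss_normalize(table).values
    levels = meta.levels
    g = np.asarray([meta.group[s] for s in meta.sample_ids])
    labels = np.asarray([levels.index(v) for v in g])
    H, p = _kruskal_rowwise(rel, labels, len(levels))
    if len(levels) == 2:
        pc = _half_min_positive(rel)
        mref = rel[:, labels == 0].mean(axis=1)
        malt = rel[:, labels == 1].mean(axis=1)
        effect = np.log2((malt + pc) / (mref + pc))
        g2 = levels[1]
    else:
        effect = np.zeros(table.n_features)
        g2 = "all"
    return _results(table, "kruskal_wallis", levels[0], g2, effect, p, adjust)


def aldex2_like(
    table: FeatureTable, meta: SampleMetadata, adjust: str = "BH",
    M: int = 128, seed: int = 42, test: str = "welch", **_,
) -> list[DAResult]:
    """Dirichlet Monte-Carlo CLR test averaged over posterior instances.

    Counts are rounded to integers; each sample's composition is drawn
    ``M`` times from Dirichlet(counts + 0.5), CLR-transformed (pseudocount
    0: draws are strictly positive), and tested per feature between groups
    (Welch t or rank-sum).  Reported ``p_value`` is the mean raw p over
    instances, ``p_adjust`` the mean of per-instance adjusted p, and the
    effect the median over instances of the between-group difference in
    median CLR (log2 scale).  Deterministic for a fixed seed.
    """
    if M < 2:
        raise DataError("aldex2_like needs M >= 2 Monte-Carlo instances")
    if test not in ("welch", "wilcoxon"):
        raise DataError(f"unknown aldex2_like test {test!r}")
    counts = np.rint(table.values)
    frac_off = np.mean(np.abs(table.values - counts) > 0.01)
    if frac_off > 0.01:
        logger.warning(
            "aldex2_like rounded non-integer abundances in %.1f%% of cells",
            100 * frac_off,
        )
    levels = meta.levels
    g = np.asarray([meta.group[s] for s in meta.sample_ids])
    labels = np.asarray([levels.index(v) for v in g])
    multi_group = len(levels) > 2
    rng = np.random.default_rng(seed)
    G, n = counts.shape
    alpha = counts + 0.5

    p_sum = np.zeros(G)
    padj_sum = np.zeros(G)
    effects = np.empty((M, G))
    m1 = labels == 0
    m2 = labels == 1
    for m in range(M):
        gamma = rng.standard_gamma(alpha.T)  # (n, G): one draw per sample
        comp = (gamma / gamma.sum(axis=1, keepdims=True)).T  # (G, n) simplex
        clr = clr_transform(comp, pseudocount=0.0)
        if multi_group:
            _, p = _kruskal_rowwise(clr, labels, len(levels))
            effects[m] = 0.0
        else:
            if test == "welch":
                _, _, p = _welch_rowwise(clr[:, m1], clr[:, m2])
            else:
                p = _wilcoxon_rowwise(clr[:, m1], clr[:, m2])
            effects[m] = (
                np.median(clr[:, m2], axis=1) - np.median(clr[:, m1], axis=1)
            ) / _LN2
        p_sum += p
        padj_sum += adjust_pvalues(p, adjust)

    p_mean = p_sum / M
    padj_mean = np.minimum(padj_sum / M, 1.0)
    effect = np.median(effects, axis=0)
    g2 = "all" if multi_group else levels[1]
    return [
        DAResult(feature=f, method="aldex2_like", group1=levels[0], group2=g2,
                 effect=float(e), p_value=float(pv), p_adjust=float(pa),
                 adjust_method=adjust)
        for f, e, pv, pa in zip(table.feature_ids, effect, p_mean, padj_mean)
    ]


def linda_like(
    table: FeatureTable, meta: SampleMetadata, adjust: str = "BH",
    pseudocount: float = 0.5, **_,
) -> list[DAResult]:
    """CLR regression with compositional-bias correction by mode centering.

    Per feature, OLS of the CLR value on the group indicator gives a slope
    and standard error.  Because CLR slopes of truly null features share a
    common offset induced by the differentially abundant ones, the mode of
    the slope distribution (Gaussian KDE, Silverman bandwidth, 512-point
    grid) is subtracted from every slope before testing.  Effect =
    corrected slope / ln 2 (log2 scale).
    """
    m1, m2, g1, g2 = _two_group_masks(meta)
    n1, n2 = int(m1.sum()), int(m2.sum())
    if n1 < 2 or n2 < 2:
        raise DataError("linda_like needs >= 2 samples per group")
    clr = clr_transform(table, pseudocount=pseudocount)
    b = clr[:, m2].mean(axis=1) - clr[:, m1].mean(axis=1)
    rss = (
        ((clr[:, m1] - clr[:, m1].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        + ((clr[:, m2] - clr[:, m2].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    )
    df = n1 + n2 - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.sqrt(rss / df * (1.0 / n1 + 1.0 / n2))
    mode = _kde_mode(b)
    b_star = b - mode
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b_star / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero_se = se == 0
    if np.any(zero_se):
        logger.warning(
            "linda_like: %d zero-variance feature(s); p set to 1",
            int(zero_se.sum()),
        )
        p[zero_se] = 1.0
    effect = b_star / _LN2
    return _results(table, "linda_like", g1, g2, effect, p, adjust)


def _kde_mode(values: np.ndarray) -> float:
    """Mode of a 1-D sample: argmax of a Gaussian KDE on a 512-point grid
    spanning [min, max].

    Bandwidth is Silverman's rule of thumb, ``0.9 min(sd, IQR/1.34)
    n^(-1/5)`` — the robust variant matters here because the outlying
    values are precisely the differentially abundant features the mode
    must ignore.  Argmax ties break toward the smallest grid value.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return 0.0
    lo, hi = values.min(), values.max()
    sd = values.std(ddof=1) if values.size > 1 else 0.0
    if lo == hi or sd == 0:
        return float(lo)
    iqr = np.subtract(*np.percentile(values, [75, 25]))
    spread = min(sd, iqr / 1.34) if iqr > 0 else sd
    bw = 0.9 * spread * values.size ** (-1.0 / 5.0)
    grid = np.linspace(lo, hi, 512)
    dens = np.exp(
        -((grid[:, None] - values[None, :]) ** 2) / (2.0 * bw**2)
    ).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


def limma_like(
    table: FeatureTable, meta: SampleMetadata, adjust: str = "BH",
    prior_count: float = 0.5, **_,
) -> list[DAResult]:
    """Empirical-Bayes moderated t on log2-CPM.

    Library sizes are effective sizes from trimmed-mean-of-M-values
    scaling (the standard compositional normalization paired with
    moderated-t pipelines), falling back to raw column sums when too few
    features are positive everywhere; a residual group-level compositional
    offset is removed by centering the log-fold-changes on their kernel
    density mode.  Per-feature residual variances are shrunk toward
    a common prior estimated by the method of moments on log variances
    (trigamma inversion); the moderated t has ``d0 + n - 2`` degrees of
    freedom.  Effect = log2-CPM slope (log2 fold change).
    """
    m1, m2, g1, g2 = _two_group_masks(meta)
    n1, n2 = int(m1.sum()), int(m2.sum())
    n = n1 + n2
    if n < 3:
        raise DataError("limma_like needs >= 3 samples in total")
    x = table.values
    lib = _effective_library_sizes(x)
    logcpm = np.log2((x + prior_count) / (lib + 2 * prior_count) * 1e6)
    b = logcpm[:, m2].mean(axis=1) - logcpm[:, m1].mean(axis=1)
    # residual compositional offset: per-sample trimming cannot fully
    # separate a strongly-changed minority when biological noise is large,
    # but the pooled log-fold-change distribution is bimodal there, so its
    # mode locates the null center precisely
    b = b - _kde_mode(b)
    rss = (
        ((logcpm[:, m1] - logcpm[:, m1].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        + ((logcpm[:, m2] - logcpm[:, m2].mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    )
    d = n - 2
    s2 = rss / d
    d0, s0_sq = _fit_variance_prior(s2, d)
    if not np.isfinite(s0_sq):
        logger.warning("limma_like: variance-prior fit failed; using ordinary t")
        s2_post = s2
        df_total = float(d)
    else:
        if np.isinf(d0):
            s2_post = np.full_like(s2, s0_sq)
            df_total = 1e6
        else:
            s2_post = (d0 * s0_sq + d * s2) / (d0 + d)
            df_total = d0 + d
    with np.errstate(divide="ignore", invalid="ignore"):
        t = b / np.sqrt(s2_post * (1.0 / n1 + 1.0 / n2))
        p = 2.0 * stats.t.sf(np.abs(t), min(df_total, 1e6))
    p[~np.isfinite(p)] = 1.0
    return _results(table, "limma_like", g1, g2, b, p, adjust)


def _effective_library_sizes(
    x: np.ndarray, logratio_trim: float = 0.3, abundance_trim: float = 0.05
) -> np.ndarray:
    """Effective library sizes from trimmed-mean-of-M-values scaling.

    Per-sample scale factors are weighted means of log2 abundance ratios
    against a reference sample, after trimming the most extreme 30% of
    log-ratios and 5% of average abundances.  The two-sided trim makes the
    factor insensitive to a minority of strongly changed features, so that
    a compositional shift is absorbed into the normalization rather than
    spread across all features.  Factors are scaled to geometric mean 1
    and applied to the raw column sums.
    """
    colsum = x.sum(axis=0)
    if np.any(colsum <= 0):
        raise DataError("all-zero sample column")
    n_samples = x.shape[1]
    if np.sum(np.all(x > 0, axis=1)) < 10 or n_samples < 2:
        return colsum
    # reference: sample whose upper quartile is closest to the mean one
    uq = np.array([np.quantile(x[:, j] / colsum[j], 0.75) for j in range(n_samples)])
    ref = int(np.argmin(np.abs(uq - uq.mean())))
    log_f = np.zeros(n_samples)
    for j in range(n_samples):
        if j == ref:
            continue
        ok = (x[:, j] > 0) & (x[:, ref] > 0)
        pj = x[ok, j] / colsum[j]
        pr = x[ok, ref] / colsum[ref]
        M = np.log2(pj / pr)
        A = 0.5 * np.log2(pj * pr)
        w = (colsum[j] - x[ok, j]) / (colsum[j] * x[ok, j]) + (
            colsum[ref] - x[ok, ref]
        ) / (colsum[ref] * x[ok, ref])
        lo_M, hi_M = np.quantile(M, [logratio_trim, 1 - logratio_trim])
        lo_A, hi_A = np.quantile(A, [abundance_trim, 1 - abundance_trim])
        keep = (M >= lo_M) & (M <= hi_M) & (A >= lo_A) & (A <= hi_A) & (w > 0)
        if keep.sum() < 3:
            continue
        log_f[j] = np.sum(M[keep] / w[keep]) / np.sum(1.0 / w[keep])
    log_f -= log_f.mean()  # geometric mean of factors = 1
    return colsum * 2.0**log_f


def _trigamma_inverse(x: float) -> float:
    if x <= 0:
        return float("inf")
    if x > 1e7:
        return 1.0 / math.sqrt(x)
    if x < 1e-6:
        return 1.0 / x
    y = 0.5 + 1.0 / x
    for _ in range(60):
        tri = float(special.polygamma(1, y))
        dif = tri * (1.0 - tri / x) / float(special.polygamma(2, y))
        y += dif
        if abs(dif) / y < 1e-10:
            break
    return y


def _fit_variance_prior(s2: np.ndarray, d: int) -> tuple[float, float]:
    """Method-of-moments fit of (d0, s0^2) on log sample variances."""
    ok = s2 > 0
    if ok.sum() < 2:
        return float("inf"), float("nan")
    e = np.log(s2[ok]) - float(special.digamma(d / 2.0)) + math.log(d / 2.0)
    e_mean = float(e.mean())
    e_var = float(e.var(ddof=1)) - float(special.polygamma(1, d / 2.0))
    if e_var <= 0:
        d0 = float("inf")
        s0_sq = math.exp(e_mean)
    else:
        d0 = 2.0 * _trigamma_inverse(e_var)
        s0_sq = math.exp(
            e_mean + float(special.digamma(d0 / 2.0)) - math.log(d0 / 2.0)
        )
    return d0, s0_sq


def css_like(
    table: FeatureTable, meta: SampleMetadata, adjust: str = "BH",
    quantile: float = 0.5, **_,
) -> list[DAResult]:
    """Cumulative-sum scaling normalization, then Welch on log2(n+1).

    Each sample is scaled by the sum of its counts at or below its own
    ``quantile``-quantile of nonzero values (robust to a few dominant
    features), multiplied by 1000.  Effect = difference of group means of
    log2(normalized + 1).
    """
    m1, m2, g1, g2 = _two_group_masks(meta)
    x = table.values
    scale = np.empty(x.shape[1])
    for j in range(x.shape[1]):
        col = x[:, j]
        nz = col[col > 0]
        if nz.size == 0:
            raise DataError(f"sample {table.sample_ids[j]!r} has no nonzero count")
        q = np.quantile(nz, quantile)
        scale[j] = col[col <= q].sum()
        if scale[j] == 0:
            raise DataError(
                f"cumulative-sum scaling factor is 0 for sample {table.sample_ids[j]!r}"
            )
    norm = np.log2(x / scale * 1000.0 + 1.0)
    t, df, p = _welch_rowwise(norm[:, m1], norm[:, m2])
    effect = norm[:, m2].mean(axis=1) - norm[:, m1].mean(axis=1)
    return _results(table, "css_like", g1, g2, effect, p, adjust)


def maaslin2_like(
    table: FeatureTable, meta: SampleMetadata, adjust: str = "BH", **_,
) -> list[DAResult]:
    """Per-feature linear model on log2 relative abundance with covariates.

    TSS-normalized abundances are log2-transformed with a per-feature
    half-minimum-positive pseudocount; the group indicator plus any
    metadata covariates enter an additive OLS design.  Effect = group
    coefficient (log2 scale).
    """
    m1, m2, g1, g2 = _two_group_masks(meta)
    rel = tss_normalize(table).values
    pc = _half_min_positive(rel, axis=1)
    pc = np.where(np.isfinite(pc), pc, 1e-12)
    y = np.log2(rel + pc[:, None])

    n = rel.shape[1]
    cols: list[np.ndarray] = [np.ones(n), m2.astype(float)]
    names = ["(intercept)", "group"]
    if meta.covariates is not None:
        for cname in meta.covariates.columns:
            col = meta.covariates[cname]
            if pd.api.types.is_numeric_dtype(col):
                cols.append(col.to_numpy(dtype=float))
                names.append(cname)
            else:
                dummies = pd.get_dummies(col, prefix=cname, drop_first=True)
                for dcol in dummies.columns:
                    cols.append(dummies[dcol].to_numpy(dtype=float))
                    names.append(dcol)
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        offenders = [
            names[j] for j in range(2, X.shape[1])
            if np.linalg.matrix_rank(np.delete(X, j, axis=1)) == rank
        ]
        raise DataError(f"collinear covariate column(s): {offenders or names[2:]}")
    XtX_inv = np.linalg.inv(X.T @ X)
    beta = y @ X @ XtX_inv.T  # (G, p)
    resid = y - beta @ X.T
    df = n - X.shape[1]
    if df <= 0:
        raise DataError("maaslin2_like design leaves no residual degrees of freedom")
    s2 = (resid**2).sum(axis=1) / df
    se = np.sqrt(s2 * XtX_inv[1, 1])
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, 1] / se
        p = 2.0 * stats.t.sf(np.abs(t), df)
    zero = se == 0
    p[zero & (beta[:, 1] == 0)] = 1.0
    p[zero & (beta[:, 1] != 0)] = 0.0
    p[~np.isfinite(p)] = 1.0
    return _results(table, "maaslin2_like", g1, g2, beta[:, 1], p, adjust)


def lefse_like(
    table: FeatureTable, meta: SampleMetadata, adjust: str = "BH",
    alpha_screen: float = 0.05, lda_threshold: float = 2.0, **_,
) -> list[DAResult]:
    """Kruskal-Wallis screen followed by a univariate log10 effect score.

    Abundances are scaled to counts-per-million per sample.  Features
    passing the KW screen (raw p < ``alpha_screen``) receive the biomarker
    score ``sign(m2 - m1) * log10(1 + |m2 - m1|)`` on group mean CPM;
    others score 0.  Downstream callers flag a feature when |score| >=
    ``lda_threshold`` and the screen passes.
    """
    m1, m2, g1, g2 = _two_group_masks(meta)
    cpm = tss_normalize(table).values * 1e6
    labels = m2.astype(int)
    _, p = _kruskal_rowwise(cpm, labels, 2)
    mean1 = cpm[:, m1].mean(axis=1)
    mean2 = cpm[:, m2].mean(axis=1)
    diff = mean2 - mean1
    score = np.sign(diff) * np.log10(1.0 + np.abs(diff))
    score = np.where(p < alpha_screen, score, 0.0)
    return _results(table, "lefse_like", g1, g2, score, p, adjust)


METHODS: dict[str, Callable[..., list[DAResult]]] = {
    "welch_t": welch_t,
    "kruskal_wallis": kruskal_wallis,
    "aldex2_like": aldex2_like,
    "linda_like": linda_like,
    "limma_like": limma_like,
    "css_like": css_like,
    "maaslin2_like": maaslin2_like,
    "lefse_like": lefse_like,
}

# Methods with a built-in treatment of >2 groups (no pairwise expansion).
_OMNIBUS_CAPABLE = {"kruskal_wallis", "aldex2_like"}


def pathway_daa(
    table: FeatureTable,
    meta: SampleMetadata,
    method: str = "linda_like",
    adjust: str = "BH",
    seed: int = 42,
    params: Optional[dict] = None,
) -> list[DAResult]:
    """Run one registered DA method over an aligned table/metadata pair.

    Features with zero total abundance are dropped (logged).  With more
    than two group levels, two-group methods are run pairwise against the
    reference group and p-values are adjusted across the pooled
    (feature x contrast) set; ``kruskal_wallis`` and the multi-group
    branch of ``aldex2_like`` test omnibus instead.
    """
    if method in RESERVED_METHODS:
        raise DataError(f"method {method!r} is reserved but not implemented")
    if method not in METHODS:
        raise DataError(
            f"unknown method {method!r}; available: {sorted(METHODS)}"
        )
    if adjust not in ADJUST_METHODS:
        raise DataError(f"unknown adjustment method {adjust!r}")
    if set(table.sample_ids) != set(meta.sample_ids):
        raise DataError("table and metadata are not aligned; call align() first")
    meta.validate_for_da()
    totals = table.values.sum(axis=1)
    if np.any(totals == 0):
        dropped = [f for f, t in zip(table.feature_ids, totals) if t == 0]
        logger.warning("dropping %d zero-total feature(s): %s%s",
                       len(dropped), dropped[:5], "..." if len(dropped) > 5 else "")
        keep = [f for f, t in zip(table.feature_ids, totals) if t > 0]
        if not keep:
            raise DataError("all features have zero total abundance")
        table = table.select_features(keep)

    params = dict(params or {})
    params.setdefault("seed", seed)
    fn = METHODS[method]
    levels = meta.levels
    if len(levels) == 2 or method in _OMNIBUS_CAPABLE:
        return fn(table, meta, adjust=adjust, **params)

    # pairwise contrasts vs the reference, pooled adjustment
    all_results: list[DAResult] = []
    for level in levels[1:]:
        keep = [
            s for s in meta.sample_ids
            if meta.group[s] in (meta.reference_group, level)
        ]
        sub_meta = meta.select_samples(keep)
        sub_table = table.select_samples(keep)
        all_results.extend(fn(sub_table, sub_meta, adjust="none", **params))
    pooled = adjust_pvalues([r.p_value for r in all_results], adjust)
    for r, pa in zip(all_results, pooled):
        r.p_adjust = float(pa)
        r.adjust_method = adjust
    return all_results


def results_to_frame(results: Sequence[DAResult]) -> pd.DataFrame:
    """Serialize DA records to a data frame (TSV column order)."""
    return pd.DataFrame(
        [
            {
                "feature": r.feature, "method": r.method, "group1": r.group1,
                "group2": r.group2, "effect": r.effect, "p_value": r.p_value,
                "p_adjust": r.p_adjust, "adjust_method": r.adjust_method,
            }
            for r in results
        ]
    )


def write_da_results(results: Sequence[DAResult], path) -> None:
    results_to_frame(results).to_csv(path, sep="\t", index=False)
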