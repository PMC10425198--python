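# Methods

This note records the models, parameter choices and numerical conventions
behind `picoda`, and what the synthetic benchmark does and does not
establish.

## Data model

A profile is a feature-by-sample matrix of non-negative real predicted
abundances (PICRUSt2 emits non-integers; values are kept as reals, and
methods that conceptually need counts round internally). Feature
namespaces (KO, EC, MetaCyc, KEGG pathway) are inferred from identifier
patterns, with a hint parameter to override. After `align()`, the
abundance table's sample order is canonical and metadata is reordered to
match, so downstream output is deterministic.

Pathway aggregation sums member-KO abundances without weighting. A KO in
several pathways counts fully in each: predicted gene-family abundance is
additive, and fractional assignment would require information (per-copy
pathway flux) that the prediction does not carry. All-zero pathways are
dropped by default to avoid degenerate rows in testing. The reference
snapshot's version string is written into output headers because pathway
membership drifts between database releases.

## Differential abundance

All methods share one contract: aligned table + metadata in, one record
per feature (per contrast) out, with a log2-scale effect, a two-sided
raw p and an adjusted p. "Significant" downstream means adjusted
p < 0.05 — a field convention, exposed as a parameter everywhere.

Input scale is a per-method decision:

* `welch_t`, `linda_like`, `aldex2_like` work on CLR-transformed data
  (pseudocount 0.5 for the first two; the Dirichlet draws of
  `aldex2_like` are strictly positive so its CLR uses no pseudocount).
* `kruskal_wallis` and `lefse_like` use relative abundances (TSS / CPM);
  ranks make within-sample scaling immaterial, but TSS removes depth.
* `limma_like` uses log2-CPM with TMM effective library sizes.
* `css_like` normalizes by the cumulative sum up to the per-sample median
  of nonzero values (quantile exposed, default 0.5), times 1000.
* `maaslin2_like` uses log2 of TSS with a per-feature half-minimum-
  positive pseudocount; covariates from the metadata enter additively,
  and a rank check rejects collinear designs naming the offending
  columns.

Compositional bias. When a minority of features genuinely changes,
renormalization imposes an opposite shift on everything else. Two
corrections appear in the suite:

* `linda_like` estimates the shared offset as the mode of the per-feature
  CLR slopes — null features pile up at the offset, changed features sit
  apart — and subtracts it before testing. The mode is the argmax of a
  Gaussian KDE on a 512-point grid spanning [min, max]; bandwidth is
  Silverman's rule of thumb, `0.9·min(sd, IQR/1.34)·n^(−1/5)`. The
  robust (IQR-capped) variant matters: the outlying slopes are precisely
  the differentially abundant features the bandwidth must not be inflated
  by. Argmax ties break toward the smallest grid value.
* `limma_like` first applies TMM scaling (weighted mean of log-ratios
  against a reference sample after trimming 30% of log-ratios and 5% of
  average abundances). Per-sample trimming cannot fully separate a
  changed minority when biological noise is large — the per-sample
  log-ratio distributions overlap — so a residual group-level offset is
  removed by mode-centering the pooled log-fold-changes, where the
  separation is amplified by sqrt(n). Without either step the moderated
  t would systematically flag null features in spiked data.

`limma_like` moderation: per-feature residual variances are shrunk
toward a prior estimated by the method of moments on log variances
(digamma/trigamma identities; the trigamma inversion is solved by
Newton's method to 1e-10 relative tolerance). Non-positive excess
spread gives an infinite prior df (complete shrinkage); a failed fit
falls back to the ordinary t with a warning. Voom-style precision
weights are deliberately omitted: at these sample sizes moderation
dominates behavior, and the mean-variance smoother would add a fragile
component with no independent anchor here.

`aldex2_like`: counts are rounded to integers for the Dirichlet draws
(warning when >1% of cells are off by more than 0.01); each sample's
composition is drawn M times (default 128; 64 in the benchmark) from
Dirichlet(counts + 0.5). Per instance, features are tested between
groups (Welch or rank-sum) and BH-adjusted; reported p-values are means
over instances and the effect is the median over instances of the
difference in median CLR. Fixed seed ⇒ bit-identical output. With more
than two groups it tests omnibus Kruskal-Wallis per instance.

`lefse_like` replaces the original's subclass Wilcoxon stage and
multivariate LDA by a univariate score: features passing the KW screen
(raw p < 0.05) get `sign(Δ)·log10(1 + |Δ|)` on group mean CPM; features
failing the screen score 0 (the original reports no LDA score for them).

Multi-group designs: two-group methods run pairwise against the
reference level, with p-values adjusted across the pooled
feature × contrast set; `kruskal_wallis` (and the multi-group branch of
`aldex2_like`) test omnibus instead. Features with zero total abundance
are dropped with a warning before testing.

Degenerate-input conventions: both groups constant and equal → t = 0,
p = 1; constant but unequal → p = 0 with a warning; zero-variance
features in regression methods → p = 1 with a warning; all-identical
Kruskal-Wallis input → H = 0, p = 1; |rho| = 1 → p = 0.

Multiple testing is delegated to statsmodels (`fdr_bh`, `bonferroni`,
`holm`, `fdr_by`); the test suite checks BH and Holm against independent
brute-force step procedures.

## Comparisons

Cross-method consensus reports significant-set sizes, the features
significant in all methods, per-method unique features, and pairwise
Jaccard similarity (defined as 1 when both sets are empty: the methods
agree that nothing is there).

Cross-metagenome comparison restricts all sources to their shared
features — the intersection, not a union padded with zeros, which would
fabricate rank ties — concatenates samples with the source as the group
factor, runs one DA method, and computes Spearman correlations per
matched sample name across features, averaged into a per-pair mean rho.
Correlating matched samples (rather than grand means) preserves
sample-level signal; the alternative can be added without changing the
data model.

## Visualization layers

Every figure is computed as a serializable layer first and drawn second,
so rendering can never alter a plotted value and tests never touch
pixels.

* Errorbar: TSS means ± SEM per group for features significant at the
  threshold, annotated with effect and adjusted p. SEM (not SD) is shown
  because the plot compares group means. At most 30 features are drawn —
  more is unreadable — and the error message names the count and the
  `select` remedy. Ordering is by adjusted p, name, or group of maximal
  abundance, ties broken by feature ID.
* PCA: TSS, feature-centering, SVD over samples. No per-feature variance
  scaling by default (relative abundances already share a scale); a
  `scale` flag exposes the alternative. Variance fractions are
  eigenvalue shares; the figure draws 95% normal-theory ellipses
  (chi-square, 2 df) per group.
* Heatmap: per-row z-scores with the sample (ddof = 1) standard
  deviation; constant rows become zeros with a warning. Columns are
  ordered by group then sample ID — metadata-driven, not clustered.

## Synthetic generator

The generator emulates a two-group predicted-profile study: one baseline
composition drawn log-normal(0, 1) over KOs and normalized; a chosen
fraction of features multiplied by 2^effect in non-reference groups with
renormalization; per-sample depths Poisson(depth_mean); counts from a
gamma-Poisson mixture (variance μ + φμ²; φ = 0 gives exact multinomial
sampling). Defaults: 500 features, 20 samples/group, 10% spiked at log2
effect 2, depth 50,000, dispersion φ = 0.4 (a biological CV of ≈ 65%,
typical of gut functional profiles), seeds {1, 2, 3} for the benchmark.
Feature IDs are drawn from the packaged KO universe so aggregation is
exercisable end to end.

Renormalization makes the non-spiked features carry a genuine negative
shift on the relative-abundance scale (factor 1/1.3 at the defaults).
This is intentional: it is the bias that mode centering must absorb, and
it is why empirical FDR is benchmarked at 0.10 rather than the nominal
0.05 for methods without an explicit correction. A consequence worth
knowing: the spiked TSS ratio is 2^effect/1.3, not 2^effect, so effect
recovery on the TSS scale is only clean when the spiked fraction is
small.

What passing the benchmark shows: calibration, FDR control, power and
effect recovery under independent gamma-Poisson noise around a single
baseline composition. What it does not show: robustness to correlated
features (co-occurring taxa drive correlated KOs), batch effects,
longitudinal structure, or the prediction error of PICRUSt2 itself — the
generator treats predicted abundances as the ground truth data-generating
scale.

## Packaged reference snapshot

The KO→pathway map and annotation tables are deterministic synthetic
stand-ins (KEGG-style identifiers and real pathway names/classes,
generated memberships and descriptions), pinned under a version string
and regenerable via `scripts/make_reference_snapshot.py`. Real KEGG
content is licensed and drifts between releases; a pinned synthetic
snapshot keeps every test hermetic. Analyses of real data should supply
a current export via `load_reference_map(path)`.

## Known limitations

* No negative-binomial GLM methods (DESeq2/edgeR-style); their registry
  names are reserved and error clearly.
* Covariates are supported only by `maaslin2_like`; no paired or
  longitudinal designs.
* Annotation is offline-only; the online KEGG hook is a stub.
* BIOM input and stratified (`pred_metagenome_contrib`) output are out
  of scope; tables are TSV/CSV only.
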