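# Methods

This note documents the statistical model, the estimators, the synthetic
data generator and the numerical choices behind `consensusde`, including
where the design was genuinely open and what the implemented choices do and
do not guarantee.

## Count model and normalization

Counts are negative binomial with gene-wise dispersion,
`c_gj ~ NB(μ_gj, φ_g)`, `var = μ + φμ²` (the parameterization of the
count-based DE frameworks this pipeline follows). Library scaling uses
relative log expression: the reference is the gene-wise geometric mean over
genes positive in every library, each library's raw factor is the median of
its count/reference ratios, and factors are rescaled to geometric mean 1.
The effective library size is `size_factor × geometric mean of raw library
sums`; this equals the familiar "raw sum × normalization factor" form and
makes counts-per-million comparable across libraries of different depth.
When a computation needs exchangeable libraries (conditional dispersion
estimation, the exact test), counts are rescaled to the mean effective size
and rounded half-to-even ("pseudo-counts"); the simple rescaling is used
rather than full quantile adjustment, a deliberate simplification whose
calibration is covered by the null-simulation tests.

Low-count filtering removes genes with fewer than `min_total = 10` reads
summed over the libraries *entering the analysis at hand*; each of the 256
4vs4 selections therefore has its own filtered gene universe, as does the
16-library analysis. `log_cpm` uses a prior count of 0.5 and a +1 on the
effective size (both configurable).

## Dispersion estimation

The common dispersion maximizes the summed per-gene *conditional*
log-likelihood given group totals on pseudo-counts, by golden-section
search on log φ over [1e-8, 10] to tolerance 1e-6. Conditioning removes
the group means exactly and avoids the (n−1)/n downward bias of plain
profile likelihood — with 8 libraries per group that bias would be ~12%,
material at the accuracy the recovery tests demand.

Gene-wise dispersions maximize the per-gene conditional likelihood plus
`prior_df / residual_df` times the across-gene mean likelihood
(weighted-likelihood empirical-Bayes shrinkage; prior_df defaults to 10).
The shared term is evaluated through a cubic-spline interpolant on a dense
log-φ grid (257 points by default), so the infinite-prior limit recovers
the common value to well under 1e-4 while keeping the per-combination cost
of the 256-run strategy acceptable.

The conditioning groups differ by strategy, and this matters:

* 4vs4 subsets (one pool per site): groups are the invasion categories, so
  between-site variance inflates φ. This is intentional — sites are the
  biological replicates of a category there, and the inflation is exactly
  why the 4vs4 strategy is conservative under site heterogeneity.
* 8vs8 / random-effects (both pools present): groups are the sites, so φ
  reflects within-site replication only, matching what a design-based
  (Cox–Reid) estimator would measure after fitting site means.

## The exact test

For two groups of equalized libraries the null distribution of one group's
total A given the grand total T is free of the unknown mean: it is the
negative-hypergeometric law obtained from convolving NB totals. Two-sided
p-values sum all outcomes whose conditional probability does not exceed the
observed one, with a relative tie tolerance of 1 + 1e-12 (the
minimum-likelihood convention). The weights are computed as
`u(a) + v(T−a)` with `u, v` the per-group log-pmf pieces, which makes
mirror-image outcomes bitwise ties when group sizes are equal — without
this, floating-point noise can silently drop half the mass of a symmetric
tie. Reported fold changes add a 0.5 pseudo-count per group. Agreement
with the reference implementation (edgeR's small-p exact test) is at the
1e-12 level on shared inputs.

## The nested GLM

The 8vs8 design matrix is intercept + invasion indicator (1 = recent) +
three sum-to-zero site contrasts within each category — the full-rank
encoding of "site included in the model" with sites nested in categories
that keeps the invasion effect estimable. Fitting is IRLS with log link,
fixed dispersion, step-halving on deviance increase, at most 100
iterations, convergence at relative deviance change < 1e-8; the
`converged` flag is honest. The invasion test is the likelihood-ratio test
(reduced model drops the invasion column; χ², 1 df; negative statistics
beyond −1e-6 raise a convergence warning and are clamped at zero).

Reported log₂ fold changes come from a second fit with a prior count of
0.125 reads (scaled by relative library size) added to every observation.
The test is untouched; the prior only keeps fold changes finite for genes
observed in a single category, where the unpenalized MLE diverges. This is
the convention of the reference GLM implementation.

## The shared-correlation (random-effects) strategy

On log₂-CPM, each gene's 16 values have covariance σ_g² times a
block-diagonal correlation matrix with off-diagonal ρ inside each site's
replicate pair. ρ is shared across genes: per gene, invasion-category
means are removed, the intra-site correlation of the residual pairs is
computed as a moment-based intraclass correlation, values are pooled on
the Fisher-z scale with a 5%-trimmed mean, and the result is clipped to
(−0.99, 0.99). The GLS fit whitens data and design with the block Cholesky
inverse and estimates the invasion contrast by OLS on the whitened system
(14 residual df). Residual variances are shrunk toward a moment-matched
scaled-F prior (the d₀, s₀² hyperparameters are fitted on log s² via
digamma/trigamma moment equations; genes with non-positive variance are
excluded; a non-positive spread excess yields an infinite prior). The
moderated t uses the posterior variance `(d₀s₀² + d s²)/(d₀ + d)` with
d₀ + d degrees of freedom.

## The consensus rule

`final_de = in_8vs8 AND (4vs4 tally ≥ ⌈0.85 × n_combinations⌉)` — 218 of
256 for the full design. The ceiling makes "more than 85%" and "at least
85%" coincide at 256. A gene filtered out of a combination counts as not
significant there (absence is a failure to detect); genes absent from an
entire analysis carry explicit flags after the union join. Genes
significant in *every* combination are reported separately
(`systematic_4vs4`). The tally histogram over 8vs8-significant genes is
emitted as the threshold diagnostic. FDR is recomputed independently
within every analysis (each combination, the 8vs8 run, the random-effects
run), because each is a complete test set.

## Enrichment and shift statistics

Overrepresentation uses the one-sided hypergeometric upper tail — the
enrichment direction of Fisher's exact test — after intersecting each term
with the background; terms with empty intersections are skipped, BH runs
across tested terms, and a two-sided option exists. The default background
is the filtered gene universe; using the DE set itself as background is
supported as a robustness check. Shift comparisons use the two-sided
Wilcoxon rank-sum test with midranks: exact enumeration when both samples
have ≤ 12 tie-free observations, otherwise the tie-corrected normal
approximation with continuity correction. The approximation's relative
accuracy degrades in the extreme tail (20–40% relative error below
p ≈ 0.02 at n = 10 per group, though absolute error stays below ~0.005);
conclusions at conventional thresholds are unaffected.

## Synthetic data generator

`simulate_dataset` draws
`c_gj ~ NB(s_j · q_g · 2^(x_j β_g + u_{g,site(j)}), φ_g)` with x_j = 1 at
recent sites; log-normal library factors `s_j` (sdlog 0.2), baselines
`q_g` (median 50 counts, sdlog 1.5), and dispersions `φ_g` (median 0.1,
sdlog 0.5 — a typical bulk biological-coefficient-of-variation spread);
Gaussian per-gene per-site effects `u` (sd `site_sd`, default 0.5, in
log₂ units — sites differing by ~1.4-fold on average, reflecting the
strong between-site variability this design contends with); and signed
planted effects for a `frac_de = 5%` subset, magnitudes |N(m, m/4)| with
m = `lfc_magnitude` = 2. DE genes from the labeled immune subset
(`frac_immune = 10%`) receive an additional +1 log₂ shift. Pool sizes are
uniform on {6,…,10} with an alternating floor/ceil sex split. All
randomness flows from one seed through counter-based (Philox) streams
split per stage, so identical configurations are bit-reproducible.

What the generator does *not* emulate: pooling noise (pool size is
metadata only — no model for it is available), sex-specific expression,
expression-dependent dispersion trends, correlated site effects across
genes (a shared-per-site option exists but is off by default; shared
effects are absorbed by normalization), and any sequence-level artifacts.
Passing tests therefore demonstrate correctness of the statistical
machinery under the stated model, not robustness to artifacts outside it.

`simulate_annotation` draws gene sets of uniform size in a given range;
enriched terms sample DE genes with odds multiplied by `enrichment_odds`.

## Numerical and design choices

* Dispersion bounds [1e-8, 10]; golden-section tolerance 1e-6 on log φ.
* BH step-up implemented directly from the definition; stable under input
  permutation; validated against an O(m²) oracle and statsmodels.
* Degenerate exact-test input (T = 0) returns p = 1, log FC = 0.
* Median over genes in RLE uses the midpoint convention for even counts.
* Combination enumeration is lexicographic over (site order, pool index);
  results never depend on hash or dict order.
* Per-combination refiltering, renormalization and re-estimated
  dispersions are the default for the 256 runs (each is a standalone
  analysis); an `inherit` mode reuses the 16-library dispersions for
  speed.
* Library order is design-table order everywhere; gene identifiers are
  opaque strings joined exactly.

## Known limitations

* The 8vs8 fixed-effects GLM tests the invasion contrast against
  within-site replication. When between-site variance is large, no
  fixed-effects reading of this nested design is calibrated for the
  *population-level* null — site effects are shared by both replicate
  pools, so replicate re-selection cannot average them away either. The
  consensus rule is the mitigation: in simulations with pure site effects
  (site_sd = 1) the 8vs8 strategy alone flags ~40% of null genes while the
  consensus call flags none. The random-effects strategy is calibrated in
  that regime but loses most of its power, mirroring its real-data
  behavior.
* The exact test's p-values are discrete and slightly conservative;
  they are approximately uniform under the null (max CDF deviation ~0.03
  at 2000 genes) but fail a literal Kolmogorov–Smirnov uniformity test, as
  all discrete tests do.
* Analyses at full transcriptome scale are CPU-bound in the 256-run
  strategy (roughly a minute per 1000 genes single-threaded); the examples
  and the acceptance script use a few hundred to a few thousand genes,
  which the generator's effect structure makes statistically equivalent
  for the properties being demonstrated.
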