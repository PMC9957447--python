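# Methods

This note records the models behind `trnkit`, the conventions and defaults
that matter, what the synthetic-data generator does and does not emulate,
and the numerical choices a maintainer would otherwise have to reverse-
engineer from the code.

## Regulatory network model

The pipeline assumes a target gene's expression is approximately a linear
function of the expression of the TFs that regulate it. Linearity is a
deliberate simplification: real TF–target relationships are nonlinear and
context-dependent, but linear models are tractable at genome scale and the
lasso's L1 penalty provides the sparsity that turns a regression fit into a
network.

**Objective and scaling.** `fit_gene_model` minimizes
`(1/2m)·RSS + λ·Σ|a|` with a free intercept, the response centered via the
intercept and TF features used on their native (log-expression) scale. The
scaling convention matters: λ and the coefficient cutoff α are only
meaningful relative to it, and the single global α applied across all TFs
presumes coefficients are comparable, which holds when features share a
common log scale. An opt-in `standardize` flag rescales features for data
where that assumption fails. Fitting is delegated to scikit-learn's
coordinate descent (`tol=1e-6`, `max_iter=10000`), whose objective matches
this convention exactly; the univariate case is verified in the tests
against the closed-form soft-threshold solution `sign(β)·max(|β|−λ, 0)`.

**Self-masking.** A TF is a gene too, so it gets its own model; its own
expression column is zeroed (not removed) before fitting, which keeps
coefficient vectors a fixed length and forces `a_jj = 0` exactly.

**Cross-validation.** λ is chosen to maximize the mean over genes of mean
out-of-fold R² under 10-fold CV. Folds are a random partition from an
explicit seed by default; a contiguous-block mode is available
(`contiguous=True`) since "alternating" fold constructions are also
defensible. The default candidate grid is geometric, 5⁻⁶ … 5 in
half-integer exponents.

**Gene filtering.** Genes with mean CV R² strictly below the 25th
percentile of the R² distribution are dropped before the final fit. The
percentile uses linear interpolation between order statistics; genes
exactly at the cutoff are retained.

**Thresholding.** Edges keep their signed weights; `|a_ij| ≥ α` with the
boundary included. Defaults λ = 0.008 and α = 0.075 are sensible for a
large log-scale compendium; on synthetic data the tests use λ = 0.01.
`match_density_alpha` finds the smallest α whose network has at most a
target edge count — exact, since the count is a step function over the
sorted coefficient magnitudes. Treatment-specific networks are refit on
each category's samples and density-matched to the global network so that
cross-condition enrichment comparisons are not confounded by density.

## Network topology

Summary statistics follow the conventions usual for near-bipartite directed
networks: diameter and clustering on the undirected projection (diameter on
its largest connected component); clustering is the mean local clustering
coefficient (the global/transitivity variant is a different statistic and
is not reported). The degree coefficient is the Pearson correlation of
undirected endpoint degrees over both orientations of every edge; for a
regular graph it is undefined and is reported as NaN with a warning rather
than 0. Expression dispersion is std/mean with sample (ddof = 1) standard
deviation; genes with nonpositive mean expression are excluded because the
ratio is meaningless there.

## GO annotation

**EASE score.** Enrichment uses the upper-tail hypergeometric probability
with the observed overlap penalized by one gene: `P(X ≥ ℓ−1)`, and p = 1
whenever ℓ ≤ 1. The penalty is implemented as "subtract one from the
overlap, keep the margins". It is conservative by construction (the tests
assert it never falls below the unpenalized tail). Terms require ≥ 2 pool
genes to be tested; the enrichment universe is the set of genes with at
least one biological-process annotation; annotations are propagated to
ancestors (true-path rule) before counting, which affects both term sizes
and specificity.

**Multiple testing.** The significant-term count t(k) that feeds the
z-score uses the raw EASE ≤ 0.05 threshold — the calibration against
random pools is itself the multiple-testing control, and it does not assume
independence across terms. BH-adjusted values are reported alongside for
each record, computed over the tested family of that pool.

**Null curves and z-scores.** μ_k and σ_k of the significant-term count
over 100 random pools are measured at sizes ⌊2^e⌋, e = 1.5, 2, …, 10, and
fitted as linear functions of k by ordinary least squares. The linear form
is an interpolation device, not a law: it is adequate when the number of
terms broad enough to be enrichable grows roughly linearly with pool size,
which holds for GO-like heavy-tailed term-size spectra as long as pool
sizes stay well below the universe size and within the sampled range.
Outside that range — pools larger than the largest sampled size, or a
universe small enough that large pools saturate the term list — the linear
extrapolation is biased and z-scores degrade; the annotation fixture in the
tests therefore keeps pools inside the sampled range of a 20,000-gene
universe. σ̂ ≤ 0 yields z = NaN with a warning. z ≥ 2 flags a TF as
significantly annotated.

**Specificity and similarity.** Specificity of a term is 1 over its
propagated annotation count; a term set takes the maximum over members.
Wang similarity uses semantic contribution factors 0.8 (is_a) and 0.6
(part_of), S-values as the max over ancestor paths of the product of edge
factors, pairwise similarity as the shared-ancestor S-value sum over the
two semantic totals, and best-match-average aggregation for term sets.

## Motif discovery

Candidate motifs are exact k-mers, k ∈ {6, 7, 8}; presence per promoter is
binary and forward-strand by default (a `both_strands` flag ORs in
reverse-complement matches, changing L and ℓ consistently); windows
containing N never match. Enrichment is the plain upper-tail hypergeometric
test. BH correction runs within each TF's family of tested motifs — motifs
absent from every promoter (L = 0) are excluded from the family since they
can never be significant (a `--global-fdr`-style pooled scope can be
obtained by correcting the concatenated hit list with `bh_correct`).

For speed, the vectorized enrichment path skips the exact tail computation
for motifs whose pool overlap is below mean + 0.5 sd of the null
hypergeometric (their p-values are far above any usable threshold) and
deduplicates identical (ℓ, L) pairs; the tests assert this path produces
exactly the same BH flags and adjusted values as the exhaustive
computation.

The rewiring null redraws each TF's target pool as a uniform random gene
set of the same cardinality (default), or permutes the pooled target
multiset (`mode="permute"`); both preserve every |out_i|.

**Information-content alignment.** A column's score is
`max_k p_ck·log2(p_ck/b_k)` with `0·log2(0/b) := 0`; a 7-mer's masked
window score sums the motif-selected symbol's contribution over 7
consecutive columns, and the ic-score is the best masked window divided by
the best unmasked window (s_max). The per-column score is implemented with
a positive sign so that conserved, over-background symbols score highest —
required for enriched motifs to align to the conserved regions of a PWM; a
`sign="literal"` variant with the leading minus is available. Background is
uniform 0.25 unless the PWM file supplies one; log base 2; window ties
break to the smallest start; a PWM shorter than the motif is an error
(skipped with a warning in batch scoring). A fully uninformative PWM
(s_max ≤ 0) yields NaN with a warning.

## Synthetic data: what it emulates, and what it does not

The generator plants exactly known structure so every stage has ground
truth:

- **Expression.** TF profiles are i.i.d. standard normal across samples;
  each target gene gets `⌈density·n_tf⌉` regulators with weights
  ±Uniform(0.2, 1.0) and Gaussian noise. Weights are bounded away from zero
  so a documented α separates planted signal from shrinkage noise —
  precision/recall against planted truth is then a meaningful acceptance
  quantity. Regulator choice is hub-biased (Pareto propensities,
  `hub_tail=1.5`) to reproduce the heavy-tailed out-degree spectrum of real
  TRNs; `hub_tail=None` gives near-equal pools. TF→TF regulation is off by
  default (keeping the OLS parameter-recovery oracle exact) and available
  via `tf_tf_density`.
- **Promoters.** Uniform-ACGT background of length 1577 bp (the median
  promoter length of the Arabidopsis set the method was built around), one
  planted motif copy per selected target at probability π.
- **GO corpus.** A toy DAG (root, three branches, leaf terms; a minority of
  part_of edges). Background term sizes follow a truncated Pareto(α=1)
  spectrum (mean rate 0.01 per gene-term, capped at 0.3) mirroring the
  strongly skewed term sizes of real GO corpora; with an α≈1 tail the
  number of enrichable terms grows roughly linearly in pool size, the
  regime the linear null calibration assumes. Each planted TF receives a
  functional program: its primary term over the whole pool at probability
  ρ, plus sibling terms over disjoint ~40-gene slices of the pool — larger
  regulons span more processes, and disjoint slices keep null counts
  near-Poisson instead of block-correlated.
- **Reference PWMs.** The planted k-mer embedded at 0.85 conservation in a
  wider uniform matrix, so the planted motif is the consensus core.

Not emulated: probe/batch effects, nonlinear or combinatorial regulation,
non-uniform promoter composition, evidence-code structure in annotations,
and the shared-ancestry correlations of real GO term memberships. Passing
tests therefore demonstrate that the statistical machinery behaves as
designed under its own assumptions — not that those assumptions hold for
any particular organism's data.

## Fixture scales used by the tests

Chosen as the smallest sizes at which each stage's statistics are in their
intended regime: parameter recovery at 20 TFs × 500 genes × 200 samples;
motif discovery at 10 TFs × 1,000 promoters (π = 0.5); annotation
calibration at 28 TFs × 20,000 genes (pools ≈ 713, inside the sampled null
sizes) with a 220-term corpus before program siblings. The calibration
check compares the fitted curves to the empirical means within twice the
applicable standard error — the sampling error of the mean or the fit's
residual standard error, whichever is larger — since a pointwise
mean-standard-error band is unattainable for any interpolating fit at
sizes where the null count is almost surely zero.

## Known limitations

- Lasso coefficients are biased toward zero; edge weights are evidence of
  direction and relative strength, not effect-size estimates.
- The z-score calibration interpolates; it is unreliable for pool sizes
  beyond the sampled null sizes (see above) and for universes small enough
  that large pools saturate the term list.
- EASE's overlap-penalty convention differs in detail from the 2×2-table
  adjustment some enrichment services use; results near the significance
  boundary can differ between tools.
- Motif matching is exact-string; degenerate motifs spread across several
  k-mers and lose power. No post-processing merges related k-mers.
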