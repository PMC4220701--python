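# Methods

This note documents the statistical models implemented in `msetkit`, the
parameters that matter and their defaults, the synthetic-data generators the
test suite exercises them with, and the numerical and design choices made
where the methodology left room.

## 1. Two-group differential expression

The model is a per-gene two-group comparison on log2-scale normalized
intensities: for gene *g*, samples in groups A and B are
`x ~ N(μ_gA, σ_g²)` and `x ~ N(μ_gB, σ_g²)`. The statistic is the pooled
two-sample t, optionally (and by default) with empirical-Bayes variance
moderation: the pooled variance `s_g²` (d residual df) is shrunk toward a
prior `s0²` with prior df `d0`,

    s̃_g² = (d0·s0² + d·s_g²) / (d0 + d),   t = (x̄_A − x̄_B) / (s̃_g·√(1/n_A + 1/n_B))

referred to a t distribution with `d + d0` df. By default `s0²` and `d0` are
estimated by moments from the distribution of log gene variances: under the
scaled inverse-chi-square prior, `var(log s²)` exceeds the pure sampling term
`trigamma(d/2)` by `trigamma(d0/2)`, which is inverted by Newton's method.
When the observed spread does not exceed the sampling term (homogeneous true
variances) the prior df is effectively infinite and every gene uses the
common variance — this keeps the null rejection rate at the nominal α in
both the homogeneous and heterogeneous regimes, which a fixed small prior df
does not (a fixed `d0 = 4` against homogeneous data is measurably
conservative, ~0.008 rejection at α = 0.01). A fixed prior df can still be
supplied, in which case the prior variance is the 10%-trimmed mean of gene
variances.

Fold change is `2^(x̄_A − x̄_B)` — the ratio of linear-scale group means
under the log model, with group A (postpartum) in the numerator. P-values
are nominal by design: the downstream enrichment test operates on
strict-cutoff significant sets (0.01 primary, 0.03 mining) and supplies its
own null; no multiple-testing correction is applied anywhere.

Degenerate inputs: a variance floor of 1e−8 keeps constant genes finite, so
a gene identical in all samples yields t = 0, p = 1, fold change 1. Probe
collapse keeps the minimum-p probe per annotated gene (stable sort for
ties) and drops unannotated probes.

## 2. MSET randomization enrichment

For a significant list of size *n* on a background of *B* unique annotated
genes and a database restricted to the background with *K* members, the
observed statistic is the match count *x*. The null is built by *R* draws of
*n* genes from the background without replacement (partial Fisher–Yates via
`Generator.choice(replace=False)`); default *R* = 10,000. The p-value is the
standard permutation estimator `(1 + #{null ≥ x}) / (1 + R)`, never exactly
zero; the plain `#{null ≥ x}/R` rule is available by config for
compatibility with the original formulation (which reports very small
values as inequalities, e.g. p < 0.0001 at R = 10,000).

Restricting the database to the background **before** both the observed and
null counts puts both on the same sample space, making the null exactly
Hypergeometric(B, K, n). The exact upper tail (scipy's `hypergeom.sf`,
log-space internally) is therefore reported alongside as `oracle_p`; the
test suite enforces agreement within `4·√(p(1−p)/R)`. Significant genes
absent from the background are dropped with a warning; a database with no
genes on the background is refused explicitly.

Batch runs derive each database's randomization stream from the master seed
plus a CRC32 hash of the database name, so per-database results are
independent of database order and of which other databases are present.
Randomization operates on unique gene symbols (case-folded), not probes.

Pooled databases follow the curation strategy of multi-source disease
lists: the union of all sources, and the genes backed by ≥k sources (k = 2
by default). The p-value-discreteness of MSET is worth noting: with small
(B, K, n) the match count takes few values, so calibration studies here use
instances with n in the hundreds, where the p distribution is fine enough
for a Kolmogorov–Smirnov uniformity check to be meaningful.

## 3. Coexpression modules

Unsigned weighted network: `a_ij = |cor(x_i, x_j)|^β` (Pearson on log2
values; unsigned is the historical default, signed `((1+cor)/2)^β` is
available). β is chosen per the scale-free criterion: connectivities
`k_i = Σ_{j≠i} a_ij` are binned (10 equal-width bins), `log10 p(k)` is
regressed on `log10 k`, and the smallest β with R² > 0.8 **and negative
slope** wins. Two guards matter in practice:

- *Connectivity floor.* Powers with mean connectivity below 2 are excluded:
  as β grows, all k → 0 and the degree distribution becomes vacuously
  "scale-free" (R² climbs above 0.8 precisely when the network has
  disintegrated), which chains the dendrogram and destroys module
  detection. If no admissible β reaches the threshold, the admissible β
  maximizing R² is used with a warning — on latent-factor data (which is
  not scale-free) this fallback is the common path, and module recovery
  does not depend on reaching the threshold.

Topological overlap: `t_ij = (Σ_{u≠i,j} a_iu a_uj + a_ij) /
(min(k_i,k_j) + 1 − a_ij)`, diagonal 1; entries provably in [0, 1].
Modules come from average-linkage hierarchical clustering on 1 − TOM:

1. *Static quantile cut* at the 0.99 quantile of merge heights.
2. *Eigengene-guided refinement.* A cluster is recursively split while both
   dendrogram children hold at least `min_module_size` (30) genes and their
   eigengenes differ by ≥ the merge threshold (1 − cor ≥ 0.25). This uses
   exactly the merge criterion, so refinement never undoes what merging
   would rejoin; it repairs the static cut's one failure mode (the top
   merge joining two genuine modules, which no bottom-up step can split).
3. *Size and cohesion filter.* Clusters below 30 genes are unassigned.
   A surviving cluster is kept only if the median |cor(gene, eigengene)|
   is ≥ 0.6: on structureless data a static cut always produces some large
   cluster, but its in-sample gene–eigengene correlations concentrate near
   √(explained PC1 variance of noise) ≈ 0.4–0.55 at 12 samples, while
   modules planted at loading 0.8 sit near 0.8 — the 0.6 bar separates the
   two distributions with margin. This threshold assumes module loadings
   of ~0.7 or higher; weakly loaded real modules below that would be
   discarded, a deliberate trade of sensitivity for a clean null.
4. *Eigengene merging.* The closest module pair (1 − cor of eigengenes
   < 0.25) merges iteratively. The module eigengene is the first right
   singular vector of the gene-standardized module submatrix, unit norm,
   sign-oriented to correlate positively with the module mean profile so
   merging is deterministic.

Labels are `M1, M2, ...` in descending size; leftover genes are
`unassigned`. The transcription-factor subnetwork keeps within-module gene
pairs with at least one TF endpoint, weighted by the Pearson correlation
(|r| is the exported "significance" proxy; a t-based two-sided p per edge
is emitted for reference), sorted by |weight| — a flat TSV importable by
Cytoscape.

## 4. qPCR relative expression

The efficiency-corrected ratio of target expression between groups,
normalized to references:

    ratio = E_t^ΔCq_t / geomean_r (E_r^ΔCq_r),   ΔCq = mean Cq(virgin) − mean Cq(postpartum)

Unpaired group means define ΔCq (independent animals per group). Two
reference genes (Ywhaz and Ppia by default) combine by the geometric mean
of their per-reference ratios — the standard multi-reference extension.
Amplification efficiency defaults to 2.0 (perfect doubling), overridable
per gene; with E = 2 and clean data the ratio reduces to the classic
`2^(−ΔΔCq)`. Significance is a sample-label randomization test: group
labels are permuted over samples (each sample keeps its full Cq profile,
preserving within-sample gene covariance), the log ratio is recomputed, and
the two-sided p is `(1 + #{|log null| ≥ |log observed|}) / (1 + iters)`,
default 2,000 iterations. The permutation stream is built on a canonical
(sorted) sample ordering, so exchanging which group is the numerator
inverts the ratio exactly and preserves the p-value bit for bit.

## 5. Synthetic-data generators

The generators emulate the statistical shape of a small two-group
microarray study of brain tissue and give every downstream stage a known
truth:

- **Universe**: `n_genes` unique symbols, `n_tf` flagged as transcription
  factors. Study-scale default 20,000 genes with 5% TFs.
- **Expression**: Gaussian noise on log2 scale (log-normal on linear —
  the standard multiplicative microarray error model), baseline
  N(8, 1.5²), residual sd 0.25, 6 samples per group. Exactly `n_de` genes
  carry a ±`effect_log2` group-mean shift (default 0.75–1.0 log2 ≈
  1.7–2-fold); the truth table lists exactly those genes. The defaults are
  chosen so planted effects are recoverable at 6/group — published studies
  of this design do not report their noise magnitude, so this calibration
  is the generator's own.
- **Gene sets**: each set of size K (hundreds of genes, e.g. 359 to match
  a published curated addiction list) gets a shared core (drawn once,
  common to all sets — curated disease lists share well-studied genes),
  then `enrichment_fraction` of the remainder from planted DE genes, then
  uniform fill from the whole universe. With fraction 0 and no core, sets
  are uniform draws, so unenriched databases follow the hypergeometric
  null exactly — this matters for type-I calibration.
- **Modules**: module genes are `λ·latent + √(1−λ²)·noise` per sample;
  the latent vector is standardized across samples so the planted
  gene–latent correlation equals λ even at 12 samples (without this, a
  latent drawn with small sample variance silently fails to plant the
  module). Within-module gene–gene correlation is λ² (0.64 at the default
  λ = 0.8).
- **Cq tables**: `Cq = base − log_E(expression) + noise`, base uniform in
  20–28 cycles, noise sd 0.15 cycles, 10 samples per group, references
  planted at ratio exactly 1.

What the generators do **not** emulate: probe-level effects and
summarization, batch/array effects, correlated noise between genes outside
planted modules, heavy-tailed intensities, or real database curation bias.
Passing tests therefore demonstrate the correctness and calibration of the
statistical machinery under its stated model, not robustness to real-world
artifacts.

All draws descend from a single master seed through named substreams
(`SeedSequence` with CRC32-hashed stage names), so full pipeline runs are
bit-reproducible and independent of stage order.

## 6. Problem sizes and runtime

The test suite and the acceptance script use: oracle-agreement studies at
B = 1000, K = 100, n = 50, R = 10,000 over 100 seeds; null calibration over
200 simulate→DE→MSET chains at B = 5,000; the enrichment power pattern at
B = 20,000 with five enriched plus three control databases over 50 seeded
runs at R = 10,000; module recovery over 20 seeds of the 60/50-gene
two-module generator at 12 samples; qPCR recovery over 100 simulations at
10/group; and determinism on a 5,000-gene full pipeline run executed twice.
The whole suite completes in a few minutes on one CPU.

## 7. Known limitations

- The moderated test approximates the reference empirical-Bayes treatment
  in behavior, not in its exact internals (no trend fitting, no robust
  estimation against variance outliers).
- The tree cut is not the Dynamic Hybrid algorithm; module boundaries on
  real data will differ from the R implementation's, and weakly cohesive
  modules (median gene–eigengene correlation below 0.6) are deliberately
  discarded.
- Module counts are not an invariant of the method: on data whose latent
  factors are correlated by chance above the merge threshold, two planted
  modules legitimately merge — at 12 samples this happens in a few percent
  of draws.
- The qPCR model has no standard-curve fitting, no per-well replicates and
  no outlier handling; efficiencies must be supplied if they deviate
  from 2.
- MSET is membership-only by design: no rank weighting, no
  expression-level weighting, and removal of one or two genes from a
  thousand-gene list moves p by less than Monte-Carlo error.
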