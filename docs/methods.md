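# Methods

This note records the statistical model, the estimators, the synthetic-data
design, and the numerical and design choices behind `treegwas`, at the level
of detail a user needs to judge what the package's validation does and does
not establish.

## Generative model

Traits are generated from a tree of standardized latent variables. A
non-root node `v` with parent `u` and standardized loading `λ ∈ [−1, 1]`
is

    v = λ·u + g_v + e_v,      Var(v) = 1,

where `g_v = Σ_j β_j x_j` sums the planted effects of SNPs targeted at the
node (`x_j` standardized genotypes, independent biallelic SNPs with
frequencies drawn uniformly from the configured MAF range) and `e_v` is a
Gaussian disturbance whose variance is solved so each node has exactly unit
variance; a configuration whose path-plus-effect variance exceeds 1 is
rejected. Leaf traits can optionally be discretized to a k-point ordinal
scale (default 9) by equal-probability quantile thresholds — the
questionnaire gives no generative model for scale use, so measurement error
is plain Gaussian plus discretization.

The implied marginal effect of a SNP at node `n` on leaf `i` is the planted
effect times the product of loadings from `n` down to `i`; the implied
genetic covariance, heritability, phenotypic correlation and rg matrices
are computed exactly and returned as ground truth with every simulated
dataset.

Two generation paths exist: a cohort path (dosages in {0,1,2}, phenotypes,
for the residualize-and-scan stage) and a summary-level fast path in which
each SNP's estimate vector across traits is drawn multivariate-normal
around the true marginals with sampling covariance `ρ_P / N` — the
full-sample-overlap model of one cohort analysed for all traits.
Independent cohorts are simulated by separate calls with distinct seeds.
Deliberately not modelled: LD, relatedness, ascertainment/selection bias,
and response-style questionnaire effects. Passing tests therefore
demonstrate estimator correctness under the stated sampling models, not
robustness to LD structure or biased sampling in real cohorts.

## Estimators

**Association scan.** OLS residualization on an intercept plus covariates
(rank checked, collinear columns named), then per-SNP simple regression
with t-distributed p-values (df = n − 2). SNPs at MAF strictly above 0.001
are kept. No relatedness correction: synthetic cohorts are unrelated, and
the residualize-then-scan structure preserves the two-stage interface.

**Heritability and genetic correlation.** With independent SNPs, LD scores
are constant and LD-score regression degenerates to the moment estimator

    ĥ² = M (mean χ² − a) / N,   a = 1,
    ĝcov = M (mean z_a z_b − ρ_s) / √(N_a N_b),   r̂g = ĝcov / √(ĥ²_a ĥ²_b).

The sample-overlap offset `ρ_s` (the expected null cross-trait z-product)
is unidentifiable without LD variation, so it is taken from the study
configuration (it equals the phenotypic correlation under full overlap and
0 for disjoint cohorts); a bottom-decile-χ² empirical estimator is provided
as a documented heuristic. SEs are delete-one-block jackknives over 200
contiguous blocks (configurable). Two properties of this estimator worth
knowing: its *absolute* SE grows like √M at fixed total h² (the mean χ² is
rescaled by M) — it is the relative SE that shrinks as 1/√M when the
per-SNP effect density is fixed; and a factor-level GWAS statistic carries
an effective `N = 1/SE²` column so the same moment machinery applies on the
factor's unit-variance scale.

**Effective number of tests.** Eigenvalues of the rg matrix, negatives
clipped to zero (noisy rg matrices are often non-PSD; clipping is
conservative), smallest k whose cumulative share reaches the target (ties
resolve downward: a 20×20 identity at 0.95 gives 19). The study-wide
threshold is the genome-wide alpha divided by k.

**Hierarchy.** Ward-D2 on `d = √(2(1−rg))`. The group cut is automated
(the human "visually defined" step is not reproducible): by default the
dendrogram is cut at the largest gap between consecutive merge heights,
falling back to all-singletons when the heights are near-uniform (within
5% — the signature of no structure, e.g. an identity matrix); height and
count cuts are exposed. Single-factor models are fit by unweighted least
squares on the off-diagonal correlations, three seeded starts
(eigenvector-based, constant, jittered), sign fixed so the largest loading
is positive. CFI is approximated by scaling the ULS discrepancy with the
effective sample size against the independence model,
`CFI = 1 − max(χ²_m − df_m, 0)/max(χ²_0 − df_0, χ²_m − df_m, 0)`; SRMR is
the RMS off-diagonal residual. Gates: CFI > 0.9 and SRMR < 0.1. A factor
with fewer than two salient loadings (|λ| > 0.1) is degenerate — "no
common factor" — and its solution is canonicalized to the zero vector
(the off-diagonal ULS objective cannot distinguish single-indicator
solutions). Misfitting groups lose their largest-mean-residual item one at
a time, dissolving below three items. Two-indicator groups use the
equal-loading √r convention (under-identified, flagged) and are only formed
when |rg| > 0.05, so independent top-level factors are not joined under a
spurious super-factor. Factors with rg > 0.9 merge (connected components,
then a refit over the union). Iteration stops at four levels or when the
node count stops decreasing.

**Factor GWAS.** `β̂_F = Σλᵢβ̂ᵢ / Σλᵢ²` with
`SE²_F = λᵀVλ / (Σλᵢ²)²`, V the per-SNP sampling covariance of the child
estimates built from the sampling-error correlations and per-SNP SEs;
sampling correlations are propagated analytically to factor level
(`λ_aᵀ R_ab λ_b`, normalized) so higher levels and the decomposition reuse
them. One structural property matters for study design: a SNP acting only
on one child still moves the factor composite by `λᵢ/Σλ²` of its effect.

**Locus definition.** Seeds at p < 10⁻⁵ per chromosome; a split occurs only
when consecutive seeds are *strictly* more than 250 kb apart (an exact
250,000 bp gap does not split). Locus bounds are the min/max member
positions (no padding is defined); significance requires one member below
the study-wide threshold; overlapping per-trait loci merge transitively.
Sub-loci group traits whose top SNPs coincide or have r² > 0.8 — a
deliberately simple stand-in where a co-localization backend could plug in,
producing the same data shape. Coordinates are 1-based inclusive
internally, 0-based half-open in BED export.

**Effect decomposition.** Per one-factor sub-tree (loadings frozen from
construction), the observations `(β̂₁..β̂_k, β̂_L)` are fit by GLS with
design: child i row `dv·λᵢ` on the factor effect and 1 on its own direct
effect; factor row `dv` (dv = 0.99, the dummy-latent correlation); weights
block-diagonal in V and `SE²_L`. The design is square, so the point
estimates are exact: `b_L = β̂_L/dv`, `bᵢ = β̂ᵢ − λᵢβ̂_L`; the weights
determine the reported covariance. `dv = 1` is rejected as input: the
numerical system stays invertible there, but the structural model it
emulates is under-identified. Intermediate factors obtain two conditional
estimates (child-role and parent-role); the min-|Z| one is kept — if the
effect is mediated, conditioning on the mediator shrinks it — with exact
ties resolved toward the child role. Classification uses the two-sided
Clogg test at 0.05 (the source rule states only a p-threshold; two-sided is
the conservative reading). Nodes whose marginal |z| is below the two-sided
threshold are flagged `null_marginal` (direct-only by vacuity). A
plot-layer shrink utility zeroes non-significant display effects; the
inverted convention is available behind a flag because the figure caption
it mirrors states the threshold direction ambiguously; it never touches
inference.

Known limitation: because the factor marginal is a combination of the same
children, a leaf-specific effect is structurally attenuated in its
conditional by `λᵢ²/Σλ²` (one third in a three-indicator factor). With few
indicators this places the Clogg statistic for genuinely direct effects
near the decision boundary: in the three-indicator reference study at
N = 20,000 and effect 0.05, the long-run direct-only rate is ≈0.86. With
more indicators per factor — the realistic regime — the attenuation
shrinks and the rate exceeds 0.95.

**Replication.** Estimates are divided by the response-scale range
(z-scores invariant; other affine conventions could be swapped in), alleles
flipped to the discovery orientation with mismatches dropped, pooled by
fixed-effects IVW (Cochran's Q reported, not used for filtering).
Replication = same direction and one-tailed p < 0.05 in the discovery
direction; under a null replication cohort this fires at rate 0.05 exactly.
Sign consistency uses the exact binomial tail at p = ½. Testability = the
trait's combined replication N ≥ 10,000 and the sentinel present in the
meta-analysis.

**Gene prioritization.** Five ordered rules (non-synonymous self/strong-LD;
coding/UTR self/strong-LD; intronic self or complete LD r² = 1; intronic
strong LD; closest gene). "Strong LD" is strictly r² > 0.8 (0.8 exactly
does not qualify); "complete LD" is r² = 1. Annotation comes from local
tables so the module is offline; an absent sentinel falls back to its
highest-r² proxy above the threshold, else to the closest-gene rule.
Distance ties break by smaller gene start, then identifier.

## Reference studies and problem sizes

The validation studies (module `treegwas.experiments`) fix these
conditions; the acceptance script and test suite run them as-is:

- *Parameter recovery*: two leaves under one factor, planted h² = 0.08 and
  rg = 0.6 (shared variance on the factor, `(1−rg)h²` leaf-specific),
  M = 5,000 SNPs, N = 10,000, 200 replicates; biases and 2-SE jackknife
  coverage are measured.
- *Tree recovery*: two 3-leaf factors (loadings 0.8) under one super-factor
  (loadings 0.7), leaf h² = 0.10, M = 5,000, N = 20,000, 25 replicates.
  The per-node genetic variances (root 0.1188, factor 0.0418, leaf 0.036)
  are solved so the genetic-correlation structure implies the generating
  loadings at every level *after* the leaf-to-factor composite leakage
  described above — otherwise the top-level loading estimand would be
  attenuated by construction and "recovery of 0.7" would be the wrong
  target.
- *Classification*: the same 6-leaf tree with loadings fixed at truth; one
  sentinel per replicate, drawn from the full-overlap sampling model at
  N = 20,000 with effect 0.05 planted on a factor (mediated pattern:
  all of the factor's children attenuated) or on a leaf (direct pattern:
  that leaf direct-only), 100 replicates each.
- *Oracles*: locus grouping vs an O(n²) union-find on 100 random tracks;
  the conditioning GLS vs a whitened-lstsq solver on 50 random instances;
  IVW and Clogg vs their closed forms; prioritization vs a plain-loop rule
  evaluator on 500 random bundles.
- *Demo pipeline*: 8 leaves, M = 2,000, N = 5,000, three planted sentinels;
  all stages, deterministic manifest.

These sizes keep the full suite under two minutes on one CPU while leaving
Monte-Carlo error well inside the asserted tolerances (binomial SE ≈ 1.5
points at 100 replicates, ≈ 1.3% coverage SE at 200).

## Numerical choices and degenerate inputs

Quantile discretization rejects constant input (thresholds undefined);
zero-variance SNPs are skipped with a warning while zero-variance residuals
abort the scan; exact planted fits floor the SE at a tiny positive value so
z stays finite; rg with a non-positive component heritability raises an
error carrying both components; |rg| > 1 estimates are clamped with a flag
(optional nearest-PSD projection by eigenvalue clipping); the jackknife
guards leave-out heritabilities at a small positive floor; the conditioning
solver rejects weighted designs with condition number above 10¹²; Newick
export joins multiple roots under a zero-length artificial root.
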