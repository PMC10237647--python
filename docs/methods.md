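# Methods

## Model and solver

One component of sparse multiple CCA on standardized assays
`X_1..X_S` (shared samples `n`, features `p_i`) maximizes the sum of
pairwise cross-covariances of the canonical variables `CV_i = X_i w_i`,

    sum_{i<j} w_i' X_i' X_j w_j,   subject to  ||w_i||_2 <= 1, ||w_i||_1 <= c_i,

with `c_i` in `[1, sqrt(p_i)]`.  Because the assays are standardized,
cross-covariance is the natural surrogate for cross-correlation used
throughout this family of methods; the L2 cap fixes the scale and the L1
bound induces sparsity in the weights.

The solver is block coordinate ascent.  Holding the other blocks fixed, the
objective is linear in `w_i` with gradient `g_i = sum_{j!=i} X_i' X_j w_j`,
and its exact maximizer over the constraint set is

    w_i = S(g_i, d) / ||S(g_i, d)||_2,

where `S` is elementwise soft-thresholding and `d = 0` when the
L2-normalized gradient already satisfies the L1 bound, otherwise the
unique `d > 0` at which the bound holds with equality.  `d` is found by
bisection on `[0, max|g_i|]`.  The bisection tolerance on `||u||_1 - c` is
1e-12 (up to 200 halvings): a looser tolerance (e.g. 1e-8) makes each block
update an *approximate* maximizer and produces occasional objective dips of
the same order, which would violate the monotone-ascent contract checked at
1e-9 relative slack.  Since each update is an exact maximizer, the
objective trajectory (recorded after every block update) is non-decreasing
up to floating-point rounding.

Degenerate blocks — a gradient numerically zero because an assay is
orthogonal to every other assay's current CV — yield a zero weight vector
and flag the component; extraction stops early rather than returning noise.

**Initialization.** Default is the leading right singular vector of each
assay (deterministic); `init="random"` draws a seeded unit Gaussian per
assay, which is what the seed-comparison harness uses, since with random
restarts the ascent can land in different local maxima (different planted
factors).  Convergence is declared when the largest relative L1 change of
any weight vector in one sweep falls below `tol` (default 1e-6), capped at
`max_iter` sweeps (default 100; non-convergence returns the last iterate
with a warning).

**Sign convention.** The first nonzero weight entry of assay 1 is made
positive; negating all weight vectors jointly leaves the objective
unchanged, so this is pure reporting.

**Caching.** The cross-products `X_i' X_j` are computed once per component
and reused by every block update; disabling the cache gives bit-identical
results (tested).

## Gram–Schmidt deflation

Components are extracted sequentially.  After component `k`, each assay is
deflated *by its own CV only*:

* `projection` (default): every column of the current matrix is replaced
  by its residual after projection onto the CV.  All columns of the
  deflated matrix are then exactly orthogonal to that CV, hence every later
  CV has exactly zero sample correlation with every earlier one (CVs of
  standardized input are mean-zero, so orthogonality and zero correlation
  coincide).  This is the mode that delivers the orthogonality the method
  promises.
* `rank_one`: subtracts the outer product `cv * w'` from the current
  matrix.  The classical sequential-deflation formula subtracts from the
  *original* matrix, which under repeated application would discard all
  earlier deflations; we apply it cumulatively (subtract from the current
  matrix).  Even read cumulatively, rank-one deflation only removes the
  extracted direction's mass carried by the selected features, so on data
  with correlated features later CVs remain substantially correlated with
  earlier ones (off-diagonal correlations of 0.9+ in our diagnostics).  It
  exists to reproduce and quantify that pathology, not for production use.

Reported CVs are computed against the matrices each component was fitted to
(the deflated ones); `cv_space="original"` recomputes them against the
original standardized matrices for diagnostic purposes.  Weights always
live in the original feature space.

A note on energy bookkeeping in projection mode: the Frobenius mass removed
at step `k` is `||X' cv||^2 / ||cv||^2`, and the initial squared Frobenius
norm equals the sum of these removed energies plus the final residual
(exact, Pythagoras).  The removed energy at each step is bounded below by
`||cv||^2` (Cauchy–Schwarz with `||w||_2 <= 1`), with equality only when
the CV happens to lie in a singular direction of its own assay — so the sum
of `||CV_k||^2` generally *understates* the energy removed.

## Supervision

`SSMCCA` ranks each assay's features by absolute Pearson correlation with
the outcome (point-biserial for 0/1 outcomes), keeps the top
`ceil(quantile * p)` (ties at the cut broken by feature identifier), and
runs SMCCA-GS on the retained features.  The default retained fraction is
0.8.  Selection uses the same samples as fitting, matching the design this
implements; in-sample variance explained is therefore optimistic, which is
why the evaluation module exists separately.  Covariate adjustment happens
downstream in evaluation, not inside selection.  Weight matrices are
scattered back to the full feature space with exact zeros, so transfer and
IO are oblivious to the selection.

The supervised-vs-unsupervised comparison harness in the acceptance script
uses a *stricter* retained fraction (0.2) than the 0.8 default.  The test
scenario plants a distractor factor with twice the loading scale of the
outcome-linked factor and 5% support per assay.  Because distractor
features are uncorrelated with the outcome, they rank among the null
features; retaining 80% removes only ~20% of the distractor's support,
leaving it dominant — both methods then converge to the distractor, and
there is no systematic difference to detect.  Retaining the top 20% keeps
every outcome-linked feature (their |r| is far above the null) while
removing ~84% of the distractor support, which is precisely the mechanism
outcome-guided selection is supposed to exercise.  This is an experiment
design choice, fixed before measurement and not tuned.

## Preprocessing

* **log + inverse normal**: per feature, `Phi^-1((rank - 0.5)/n)` with
  average ranks for ties.  The 0.5 offset is symmetric (tie-free features
  map to a mean-zero set) and bounded away from 0/1.  Log is monotone, so
  the composite equals the rank transform; the strict-positivity
  precondition is still enforced to catch misuse.
* **standardization**: mean 0, SD 1 with the `n-1` denominator; constants
  are stored next to trained weights so a training cohort's scaling can be
  replayed on a target cohort (`standardization="source"`), although the
  default for transfer is the target cohort's own scaling.
* **correlated-feature pruning**: pairs with squared Pearson correlation
  at or above the threshold (default 0.8) are "neighbors"; one feature with
  at least one remaining neighbor is removed per iteration.  The
  min-degree variant (`printed`) contradicts the stated goal of maximizing
  retained features — on a hub-and-spokes graph it discards the leaves and
  keeps 1 feature where removing the hub would keep 4 — so the default is
  `max_degree`, which removes the highest-degree feature.  Ties resolve to
  the lexicographically smallest id; zero-degree features are never
  candidates (otherwise the loop cannot terminate).  Both modes guarantee
  the exit invariant: no surviving pair at or above the threshold.
* **PCA-IQR outliers**: each sample's within-sample IQR across features
  (x-axis) against its score on PC1 of the standardized matrix (y-axis);
  samples with IQR above `Q3 + 3 * IQR` of the per-sample IQR distribution
  are flagged.  The fence multiplier operationalizes what is in practice a
  visual call; 3.0 is the conventional "far out" Tukey fence and flags
  under 2% of homogeneous Gaussian samples.

## Synthetic data

`generate_multiomics` draws `k` latent factors as orthonormalized Gaussian
columns `Z` (`Z'Z = I`), scales them by `sqrt(n)` so each factor has unit
sample variance, and emits per assay

    X_i = F B_i' + batch shifts + N(0, noise_sd_i^2),   F = sqrt(n) Z,

with `round(sparsity * p_i)` nonzero loadings per factor per assay, nonzero
values `N(0, loading_scale_k^2)`.  The `sqrt(n)` scaling is what makes
`loading_scale` and `noise_sd` commensurable (signal SD per feature is the
loading magnitude against noise SD 1); without it the planted signal would
sit far below the noise floor of the cross-product matrix at any stated
parameter values.  Batch effects are additive per-batch feature-wise mean
shifts — the simplest mechanism that reproduces the qualitative contrast
where PC1 locks onto an assay-specific batch axis while the cross-assay CV
ignores it.  The continuous outcome is `F @ gamma + eps` with `eps` scaled
so the population R² of the outcome on the factors equals `outcome_r2`
(default 0.5); the binary outcome is a Bernoulli draw through a logistic
link whose linear predictor variance matches the same signal fraction
against the logistic residual variance π²/3.  `generate_cohort_pair` reuses
loadings and outcome coefficients across two cohorts with independent
samples, noise and batches.

What the generator does **not** emulate: methylation beta-value
distributions, assay-specific measurement artifacts, heteroskedastic noise,
non-linear factor-outcome links, or population structure.  Passing tests
therefore demonstrate correctness of the machinery under a linear sparse
factor model, not performance on real cohort data.

Defaults (`n=300`, `p=(400,600)`, `sparsity=0.05`, `loading_scale=3`,
`noise_sd=1`, `outcome_r2=0.5`) are the study conditions used throughout
the recovery experiments; the acceptance script and tests state their sizes
explicitly where they differ (e.g. `n=500` per cohort for transfer,
`p=(200,300)` for the seed-comparison harness).

## Evaluation

Linear variance explained is OLS R²; `incremental` (default) reports
`R²(covariates + block) − R²(covariates)`, `marginal` the block alone.
Incremental r² is invariant to invertible reparameterization of the block;
rank-deficient designs drop aliased columns with a warning.  Binary
outcomes use McFadden's pseudo-R² `1 − ll(full)/ll(null)` with the null
holding covariates (incremental) or only an intercept (marginal); perfect
separation is flagged and reported as 1.  Association tests are Wald tests
on the CV coefficient in the covariate-adjusted model; significance
thresholds (e.g. Bonferroni) are the caller's.  The seeded method
comparison runs both fitters per seed and applies a paired two-sided t-test
to the per-seed r² differences (paired because both methods share each
seed), flagging significance at p ≤ 0.01.

## Numerical choices and edge cases

* Penalty default `c_i = 0.5 sqrt(p_i)` ("default"), configurable per
  assay; permutation-based penalty tuning is out of scope.
* Bisection: tolerance 1e-12 on `||u||_1 − c`, ≤ 200 halvings (see above).
* Degenerate gradient threshold: 1e-12 relative to the largest assay
  Frobenius norm.
* Equal-strength planted factors are only identifiable up to rotation (the
  objective is invariant under rotating equally strong factors), so
  recovery tests use distinct per-factor loading scales.
* PC sign convention: the largest-magnitude loading of each component is
  made positive.
* Missing values are rejected everywhere, never imputed; imputation belongs
  upstream.

## Known limitations

* In-sample selection and fitting (no internal split) makes training-set
  r² optimistic; use the transfer path for honest assessment.
* The sparse support of a fitted weight vector is governed by the L1 bound,
  not by the planted support size: whenever the bound `c` is active, the
  unit-L2 weight vector must carry at least `c²` nonzeros (Cauchy–Schwarz),
  so support *precision* against a planted support smaller than `c²` is
  structurally capped regardless of signal strength — select `c` near the
  expected support's `L1/L2` ratio if support recovery matters.
* Dense cross-products make the solver O(p_i p_j) memory per pair; at the
  10k-feature scale this is hours of CPU for tens of components, and no
  low-rank shortcut is provided.
* The rank-one deflation mode is intentionally faithful to its defects.
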