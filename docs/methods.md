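# Methods

## Model

`sparseclogit` fits L1-penalized conditional logistic regression to
individually matched data: 1:1 or 1:M matched case-control sets, or
case-crossover designs where each subject's case period is compared with
their own earlier control periods.

Subjects are grouped into N strata (matched sets), each holding one case and
M_n controls. The stratified logistic model gives subject i of stratum n an
event probability with stratum-specific intercept alpha_n:

    logit(pi_in) = alpha_n + u_in' beta,

where u_in are the p exposures and beta the log odds ratios of interest.
Conditioning on "exactly one case per stratum" removes alpha_n entirely: the
probability that the observed case is the case is

    exp(u_case' beta) / sum_l exp(u_l' beta).

Writing x_in = u_case,n − u_in (one difference row per control), the
negative conditional log-likelihood becomes

    L(beta) = sum_n log(1 + sum_{l in n} exp(−x_ln' beta)),

and the whole fit operates on the difference matrix X (sum_n M_n rows).
For 1:1 matching this is exactly a no-intercept binary logistic likelihood
on the difference rows with constant response 1 — a property the test suite
verifies against an independently coded L1 logistic fit.

The estimator minimizes L(beta) + lambda * ||beta_penalized||_1. Covariates
can be declared *forced* (confounders such as age, sex, chronic disease):
they carry zero penalty and always stay in the model.

## Algorithm

The solver is IRLS (proximal Newton) with a cyclic coordinate-descent inner
solver:

1. At the current beta compute the per-stratum denominators
   d_n = 1 + sum_l exp(−x_ln beta), the residuals r_ln = exp(−x_ln beta)/d_n,
   the diagonal weights W_ln = exp(−x_ln beta)/d_n², and the working
   response z_ln = x_ln beta + d_n. On the difference scale the weight
   matrix is diagonal — the key computational simplification (on the raw
   subject scale it is block-dense).
2. Form the p×p Gram system A = X'WX, b = X'Wz and solve the quadratic
   model (1/2) g'Ag − b'g + sum_j lambda_j |g_j| by cyclic coordinate
   descent with soft-thresholding (fixed sweep order 1..p; after a full
   sweep, sweeps cycle over the active set until stable, then a full sweep
   verifies coordinate-wise optimality). The solver touches only A and b,
   never W^(1/2)X, so memory is O(p²) regardless of sample size — this is
   what makes registry-scale N feasible. For sparse X the Gram matrix is
   accumulated row-block-wise (a numba kernel when available, scipy sparse
   products otherwise).
3. Backtracking line search on the true penalized objective along
   delta = gamma − beta, with Armijo slope
   D = g'delta + lambda(||gamma||_1 − ||beta||_1). Including the penalty
   difference in the slope is essential: with the bare g'delta the required
   decrease retains a penalty-scale term while the attainable decrease
   vanishes near the optimum, and the search jams at partial steps before
   the optimality conditions are met. D upper-bounds the directional
   derivative of the penalized objective and is strictly negative for any
   non-trivial inner solution, so accepted steps strictly decrease the
   objective. If backtracking underflows without meeting the criterion, the
   largest trial step that strictly decreased the objective is taken;
   finding no decrease along a tiny step is treated as convergence at
   floating-point resolution.
4. Stop when the relative objective change is below tau *and* the
   subgradient (KKT) residual is below kkt_tol, or when the inner step is
   below step_tol. The KKT condition matters because the objective is
   quadratically flat near the optimum: the tau test alone fires about one
   Newton iteration before the certificate holds.

For M > 1 the diagonal-weight matrix A is not the exact Hessian (the
within-stratum cross terms are dropped, and A underestimates curvature by up
to a factor d_n). The steps then overshoot and convergence is linear rather
than quadratic; the default Armijo fraction alpha1 = 0.25 makes the line
search reject the overshooting full step and settle near the exact Newton
step, which restores fast convergence in practice. For M = 1 the quadratic
model is the exact Hessian and full steps are taken.

### Numerical details

- Likelihood, gradient and weights are computed with the per-stratum
  maximum exponent factored out (log-sum-exp), so every quantity is finite
  for any finite beta.
- b = X'Wz is accumulated as X'(W∘eta + r) using the identity
  W_ln d_n = r_ln; the working response z itself (which contains d_n) is
  never materialized, so near-separated data cannot overflow it.
- Weights are floored at 1e-10 (counted and reported) to keep the Gram
  diagonal positive near separation; |x'beta| > 30 triggers a divergence
  warning.
- Partial line-search steps scale coordinates by (1 − t) instead of zeroing
  them; penalized coefficients below 1e-10 in absolute value are collapsed
  to exact zero so the reported sparsity and the sign pattern entering the
  KKT conditions are exact.
- Degenerate inputs: a penalized coordinate with zero curvature is frozen
  at zero; an unpenalized one raises (collinear forced covariate). Strata
  whose difference rows are all zero (concordant sets) contribute the
  constant log(M_n + 1); dropping them (opt-in) leaves all estimates
  unchanged.

### Defaults

| parameter | default | meaning |
|---|---|---|
| tau | 1e-8 | relative objective change declaring outer convergence |
| kkt_tol | 1e-5 | subgradient residual required at convergence |
| alpha1, alpha2 | 0.25, 0.5 | Armijo fraction, backtracking shrink |
| max_outer | 100 | outer iteration cap |
| inner_tol | 1e-9 | max coordinate change per CD sweep |
| max_inner_sweeps | 10p + 100 | CD sweep cap |
| weight_floor | 1e-10 | lower clamp on IRLS weights |
| epsilon | 0.01 | lambda_min / lambda_max |
| T | 100 | grid size |
| spacing | log | grid scale (log concentrates resolution where support changes) |

## Regularization path and model selection

lambda_max is the smallest penalty with empty penalized support: the largest
absolute gradient coordinate at the reference point — beta = 0 with no
forced covariates, otherwise the forced-only maximum conditional likelihood
fit (computed by the same IRLS machinery with the penalized block clamped at
zero, which guarantees the first path point has exactly zero penalized
support). The grid descends from lambda_max to epsilon*lambda_max and each
fit warm-starts at the previous solution. Fits that fail to converge (e.g.
separation at tiny lambda) are flagged and excluded from selection instead
of aborting the path.

Selection is likelihood-based K-fold cross-validation (default) or BIC.
CV shuffles and splits *strata*, never rows — the matched set is the
independent sampling unit — and scores each lambda by the mean held-out
conditional log-likelihood, ties toward larger lambda. BIC is
2*L + df*log(N) with N the number of strata (each stratum is one
multinomial observation of the conditional likelihood) and df the nonzero
penalized count plus the number of forced covariates. A one-standard-error
rule is deliberately not applied by default; the plain maximizer is
reported.

## Synthetic data generator

`simulate_matched` draws, per stratum, M+1 exposure vectors (binary with
given prevalence, optionally correlated within the stratum through a shared
latent exposure copied with probability rho; or gaussian), then assigns the
case by the exact conditional law: subject i is the case with probability
proportional to exp(u_i' beta). The stratum intercepts alpha_n cancel from
that probability; they are generated and echoed but provably never touch the
data, which the tests assert. This makes parameter recovery a clean test of
the estimator rather than of a sampling approximation. `simulate_case_crossover`
gives each subject n_periods exposure draws from a stationary two-state
chain with chosen marginal prevalence and lag-one correlation, then draws
the case period the same way; the default five periods mirror a 1:4 design.
With the sparse storage option, exposures are placed by drawing a binomial
count per predictor and sampling row positions without replacement — the
marginal prevalence is preserved, with negligible negative dependence
between rows at registry scale.

What the generator does *not* emulate: drug-class structure or realistic
co-prescription correlation networks, exposure misclassification, missing
data, or strata with more than one case. Passing recovery tests therefore
show the estimator handles the conditional law, sparsity and scale of such
studies — not that real registry confounding is resolved.

## Problem sizes used in the checks

The acceptance script and test suite use: 200 random small designs
(N ≤ 30, M ≤ 4, p ≤ 5) for solver-vs-convex-oracle agreement; N = 5000
1:1 strata with p = 50 and five true effects ±0.5 at prevalence 0.2
(10 seeds) for recovery and CV support selection; and one 50,000-stratum
1:4 design with 200 sparse binary predictors (prevalence 0.05) for the
large-scale 50-lambda path — chosen as a desk-scale analogue of a national
registry study while keeping the full run in the minutes range.

Oracle comparisons restrict to instances where the comparison is
well-posed: full-column-rank difference matrices (otherwise the minimizer
is not unique) and, at lambda = 0, designs whose conditional MLE exists
(no separation), checked against the independent oracle's solution staying
bounded.

## Known limitations

- Exactly one case per stratum; K:M matching with multiple cases is out of
  scope (the conditional likelihood then needs a recursive evaluation).
- No standard errors or post-selection inference; the Lasso point estimates
  and model selection are the product.
- The paths are not piecewise linear; values between grid points are not
  interpolated.
- For M > 1 the curvature model is the diagonal-weights approximation;
  convergence there is linear (fast in practice with the default line
  search, but not quadratic).
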