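# Methods

## Model

The inverse Lindley (IL) distribution is the law of `Z = 1/Y` for `Y`
Lindley-distributed with scale `θ > 0`. Writing `θ̄ = θ/(1+θ)`,

    f(z; θ) = θ θ̄ e^{−θ/z} (1+z)/z³,
    F(z; θ) = (1 + θ̄/z) e^{−θ/z},
    R(z; θ) = 1 − F(z; θ),      h(z; θ) = f/R.

The hazard is upside-down bathtub shaped (a single interior maximum),
which suits repair-time and time-between-failure data. The mean of the
IL distribution does not exist, so all reliability summaries are made
through `R(t)` and `h(t)` at user-chosen mission times rather than
through moments.

The CDF has no elementary inverse. The production quantile solves
`(1 + u/(1+θ)) e^{−u} = p` in `u = θ/z` by Brent's method on the fixed
bracket `(1e−12, 745)`; the closed form through the secondary real
branch of the Lambert-W function is kept as an independent cross-check
and as the vectorized path used by the bulk sampler. All density and
reliability evaluations run in log space; censoring factors
`log R = −θx + log(e^{θx} − 1 − θ̄x)` switch from an `expm1` form to a
factored form at `θx = 30` so neither cancellation (small `θx`) nor
overflow (large `θx`) occurs.

## Adaptive Type-I progressive censoring (AT-IPC)

`n` units start the test; at the i-th failure (i ≤ m−1) the plan
removes `S_i` survivors; planned removals stop after failure m−1; the
test always terminates at `τ`, withdrawing the `S* = n − k − Σ S_i`
units still at risk. The removals-stop-at-`m−1` rule is the one
consistent with every bundled censored fixture's S* count, including
the sub-samples whose observed failure count `k` exceeds `m−1`.

Likelihood (with `x_i = 1/z_i`, `T = 1/τ`):

    ℓ(θ) = Σ log f(z_i) + Σ S_i log R(z_i) + S* log R(τ).

The data-dependent constant `Σ log((1+z_i)/z_i³)` is retained so that
the maximized value plugs directly into information criteria. The
score and observed information are coded analytically and are
tested against central finite differences of `ℓ`.

### Spacing objective

The maximum-product-of-spacings (MPS) objective replaces the density
factors by CDF increments `D_i = F(z_i) − F(z_{i−1})` (with `z_0 = 0`)
plus the same censoring factors. Two conventions are deliberately
explicit because the definition leaves them open:

* **Boundary rule** for the (k+1)-th spacing: default
  `D_{k+1} = 1 − F(z_k)`; `F(τ) − F(z_k)` is selectable. The default is
  the convention that reproduces the bundled reference analyses.
* **Tie rule**: tied observations give zero spacings. The default
  **merge** rule collapses a tie group into one spacing (equivalently,
  drops the zero spacings); the Cheng–Amin **density** substitution
  (replace a zero spacing with `f` at the tied value) is selectable.
  The merge rule is the one that reproduces the reference fit on the
  repair-times sub-sample that contains ties; both rules are reported
  in the fit metadata so the convention in force is always visible.

Both objectives are maximized by bounded scalar search on
`(1e−6, 1e3)` (`xatol = 1e−12`) followed by a safeguarded Newton polish
on the analytic gradient; a fit is rejected unless the gradient
vanishes to `1e−6` relative to the curvature scale and the curvature is
negative. Wald variances are negative inverse second derivatives at
the optimum; `R(t)` and `h(t)` intervals use the delta method with
analytic gradients (finite-difference-checked). Wald bounds are
reported unclipped even when a lower bound is negative.

## Bayesian layers

`θ ~ Gamma(a, b)` (shape/rate); `a = b = 0` is accepted as the improper
noninformative limit, proper a posteriori whenever `k ≥ 1`. Either the
likelihood (LF) or the spacing function (SF) acts as the observed-data
factor. Sampling is random-walk Metropolis–Hastings with a normal
proposal, initialized at the MLE (LF) or MPSE (SF). The proposal sd
defaults to 0.25 × the initializer's Wald standard error; this keeps
acceptance rates in the 0.85–0.99 band on the bundled samples, the
regime the reference analyses report. Defaults are 10,000 iterations
with 2,000 burned in for simulation work and 30,000/5,000 for data
analysis. Point estimates are posterior means (squared-error loss) of
the *transformed* draws; credible intervals are equal-tailed
percentile intervals (not HPD — percentile is order-preserving under
the monotone `θ → R(t)` map and is the simpler default given that the
reference interval type is unstated). A one-dimensional adaptive
quadrature of the same unnormalized posterior provides an MCMC-free
oracle for the posterior mean; tests require agreement within
Monte-Carlo error on every fixture and both sources.

**E-Bayes.** The hyperparameters get `a ~ Beta(ε₁, ε₂)` on (0,1) —
keeping the gamma prior decreasing in θ — and `b ~ Uniform(0, c)`,
independent. The double integral over `(a, b)` is evaluated by Monte
Carlo: J hyperprior draws, one M-H chain each, E-Bayes point = mean of
the J posterior means; the E-BCI pools the draws of all J chains,
i.e. samples the hyperprior-mixed marginal posterior. Defaults
`J = 100`, inner chains 2,500/500: inner-chain Monte-Carlo error is
dominated by the hyperprior spread well before these sizes, and a full
E-Bayes fit stays in the seconds range. Elicited shapes with `a ≥ 1`
are legal but trigger a warning since the decreasing-prior rationale
no longer applies.

**Elicitation.** `G` complete pilot samples of size `n` are simulated
at a reference `θ`, estimated (MLE or MPSE), and the gamma prior's
mean and variance are matched to the sample mean and the
(G−1)-denominator sample variance of those estimates:
`ă = mean²/var`, `b̆ = mean/var`, so `ă/b̆` equals the sample mean
exactly. The beta hyperprior's `(ε₁, ε₂, c)` are user configuration:
no analogous algorithm is defined for them, so the package does not
invent one.

## Monte-Carlo harness

Metrics per method × estimand: average estimate, RMSE, mean absolute
bias, average interval length (all with the replicate count in the
denominator) plus empirical coverage and a Monte-Carlo standard error.
Replicate r draws its generator from child seed r of the master
`SeedSequence`, so results do not depend on execution order. Failed
replicates (degenerate samples, non-convergence) are skipped and
counted; more than 5% aborts the run.

Two generation mechanisms are exposed because fixing the "effective
censored-sample size" k per design is incompatible with strict AT-IPC
(where k is random):

* `atipc` — sequential conditional generation truncated at τ; the next
  failure given r units at risk beyond t is
  `F^{−1}(1 − (1−F(t)) U^{1/r})`. Realized k is reported. A brute-force
  latent-lifetime simulator (all n lifetimes drawn, bookkeeping applied
  directly) serves as its distributional oracle in tests.
* `fixed_k` (harness default) — exactly `k = m` failures are observed;
  planned removals apply only at failures at or before τ (the adaptive
  rule suspends withdrawals past the threshold) and the final
  withdrawal happens at the last failure. This is the convention under
  which the published design-table metrics are reproducible: at the
  n = 40, τ = 0.5 design with scheme (5⁴, 0¹⁶) it yields MLE
  Av.E ≈ 0.505, RMSE ≈ 0.068, MAB ≈ 0.053, whereas strict AT-IPC
  leaves a mean realized k ≈ 13 and visibly larger RMSE.

Goodness of fit on complete data: the Kolmogorov–Smirnov statistic at
the fitted CDF with the asymptotic-series p-value (this series, not
the exact small-sample law, reproduces the reference p-values), and
the A/B/CA/HQ information criteria
(`A = −2ℓ + 2p`, `B = −2ℓ + p log n`, `CA = A + 2p(p+1)/(n−p−1)`,
`HQ = −2ℓ + 2p log log n`).

## What the synthetic-data generator does and does not emulate

Simulated studies here use i.i.d. IL lifetimes under the exact
censoring mechanisms above — the same idealization the estimators
assume. Passing tests therefore demonstrate internal correctness
(estimators recover the truth under the model, intervals cover at
nominal rates, MCMC matches quadrature), not robustness to model
misspecification, covariate structure, dependence between units, or
inspection-time rounding, all of which real reliability data can
exhibit. The two bundled real datasets provide the external check that
the model fits data it was not simulated from.

## Scaled problem sizes

Default test-suite runs use reduced sizes chosen so that Monte-Carlo
tolerances (3 standard errors) stay meaningful: 200-replicate design
checks (the acceptance script uses 1,000), 16–30 hyperprior draws for
E-Bayes oracles, G = 2,000 for the elicitation check. These are the
package's own desk-scale defaults; every routine accepts larger
settings.

## Known limitations

* Only squared-error loss (posterior means); no LINEX or other
  asymmetric losses, no thinning, no adaptive MCMC.
* Only the IL family is implemented; the spacing/likelihood machinery
  is not pluggable for other distributions.
* The Wald intervals are plain asymptotic intervals; no bootstrap or
  profile-likelihood alternatives.
* `a = b = 0` with `k = 0` would be improper; samples with no observed
  failures are rejected at construction.
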