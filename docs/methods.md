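# Methods

## Model and estimating equations

Each feature (taxon) is analysed separately on a balanced panel of counts
`y_ij`, subject `i = 1..N`, time `j = 1..M`. The two-part functional
response treats the zero indicator `f1 = I(y=0)` and the count `f2 = y` as
a bivariate outcome with means

    h1 = rho + (1 - rho) exp(-mu),      logit(rho) = u' beta_u,
    h2 = (1 - rho) mu,                  log(mu)    = v' beta_v,

where `rho` is the structural-zero probability and `mu` the Poisson-part
mean. No likelihood is assumed: estimation uses generalized estimating
equations with zero-inflated-Poisson *working* variances
`Var(f1) = h1(1-h1)` and `Var(f2) = (1-rho) mu (1 + rho mu)`. The printed
source for the count-part variance is typographically ambiguous; the
standard ZIP second moment is used. Consistency of `beta_hat` requires only
the two mean models; the sandwich covariance
`B^{-1} M B^{-T}` (bread `B = (1/N) sum D_i V_i^{-1} D_i'`, meat from the
empirical per-subject score outer products, both at the plug-in estimates)
protects the Wald tests against working-model misspecification.

Per subject the 2M responses are stacked interleaved by time,
`(f1_i1, f2_i1, ..., f1_iM, f2_iM)`, so the working correlation splits
into 2x2 time blocks: `I2` within a time point and `g(|j-l|) J2` between
time points, `g(h) = alpha^h` (AR(1)) or `alpha` (exchangeable), `J2` the
all-ones block. `alpha` is a pooled moment estimate from componentwise
Pearson residuals: adjacent products summed over both components divided by
`2(K-2)` with `K = N(M-1)` adjacent pairs (AR(1)), or all ordered pairs
with `K = N M (M-1)` (exchangeable), clamped to `[0, 0.99]`.

## Positive definiteness of the block working correlation

The `J2` cross-component blocks make `R(alpha)` indefinite once `alpha`
is moderately large: the two components are uncorrelated within a time
point yet `alpha`-correlated across all pairs, which is infeasible for a
correlation matrix (for AR(1) the minimum eigenvalue is about
`2 lambda_min(Toeplitz) - 1 < 0` for `alpha` above ~1/3; exchangeable
breaks at `alpha >= 1/2`). Two mechanisms handle this:

* `build_R` itself repairs a requested matrix with the smallest continuous
  ridge lifting the minimum eigenvalue to 0.01. A stepped ridge makes the
  alternating `beta`/`alpha` iteration limit-cycle, and a barely-positive
  floor (say 1e-8) puts enormous weight on the near-null eigendirection of
  `V_i` and destabilises the scoring steps — both were observed, hence the
  continuous, well-conditioned choice.
* The solver never requests an infeasible matrix: before assembling `V_i`
  it shrinks the estimated `alpha` to the largest value keeping the block
  structure positive definite (about 0.336 for AR(1) at M=10, 0.495 for
  exchangeable; found once by bisection and cached). Monte-Carlo
  comparisons showed that ridge-repaired infeasible matrices *lose*
  efficiency relative to independence (variance ratio ~1.35 at latent
  correlation 0.9), while the shrunken feasible matrix attains the expected
  gain (ratio ~1.0). `alpha_hat` reported to the user remains the raw
  moment estimate.

## Solver

Fisher scoring `theta+ = theta + (sum D V^{-1} D')^{-1} sum D V^{-1} S`
with step halving (up to 10, requiring the estimating-function norm to
decrease), a trust-region cap of 5 on the largest step component, and a
+-30 coefficient box. `alpha` starts at 0 (one independence iteration) and
is refreshed each outer iteration with relaxation 0.5, which damps the
oscillations the plain alternating scheme occasionally exhibits.
Convergence: `max|delta theta| < 1e-6` *or* fitted means stalled below
1e-9 (see below), and `|delta alpha| < 1e-4`; at most 200 outer
iterations. Linear systems use batched dense solves per subject
(`2M x 2M`), numerically equal to explicit inversion to 1e-10.

Initial values: a small IRLS logistic fit of `I(y=0)` on `U` and a Poisson
log-linear fit of `y` on `V` restricted to positive cells.

Numerical guards, each chosen to be inert in regular problems:

* Linear predictors are clipped before the inverse link (+-30 count part,
  +-15 zero part). The tighter zero-part clip keeps `Var(f1)` well above
  the variance floor so the zero-part score stays O(1) and restoring near
  the boundary; at +-30 the floored variance and vanishing Jacobian row
  create a spurious boundary root that can trap the iteration.
* Working variances are floored at 1e-10 (`Var(f1)` underflows once
  `mu` is large, since `h1 ~ exp(-mu)`).
* Quasi-separation in the zero part (e.g. a group whose zero fraction is
  consistent with pure Poisson) sends `beta_u` along a flat clipped ray to
  infinity while every fitted mean is constant. Since the estimating
  equations identify only the means, stalling of `h` counts as
  convergence; the count-part estimates and tests are unaffected.

Degenerate features: all-zero features are flagged `all_zero` and not fit;
zero-free features are fit with the zero part disabled (`rho = 0`, count
component only, scalar correlation blocks) and flagged `no_zeros`, because
the mixture weight is unidentifiable without zeros. In that reduction the
estimator coincides with a Poisson GEE on the counts.

## Inference

The default test is the count-part group coefficient (Wald chi-square on
the sandwich block; joint tests of several `beta_v` coefficients use the
df > 1 form). Features with status other than `ok` carry no p-value and
are excluded from the Benjamini–Hochberg family. BH adjustment delegates
to `statsmodels.multipletests(method="fdr_bh")`; note the step-up adjusted
values are order-preserving but not idempotent under re-adjustment.

## Simulator

Two conditions (control/treatment), features independent of one another.
Per feature and subject a latent normal vector over the M time points with
AR(1) or exchangeable correlation `rho` is pushed through the normal CDF
and the exact ZIP quantile function (via the transformed uniform
`(u - rho0)/(1 - rho0)` and the Poisson quantile), so margins are exactly
ZIP while serial dependence is controlled separately — the latent `rho` is
attenuated on the count scale (copula 0.6 induces residual lag-1
correlation around 0.45-0.5).

Defaults define the evaluation design: 25 subjects per condition, M = 10,
1000 features with 200 differentially abundant, `rho` in {0.3, 0.6, 0.9}.
Quantities the design leaves open are fixed once: baseline means `mu0`
log-uniform on [1, 50] (typical genus-level scale after rarefaction);
structural-zero link `rho0 = expit(0 - 0.5 log mu)` so rarer taxa have
more excess zeros (zero fractions ~0.12-0.5 across the mean range);
differential features grow linearly `mu0 (1 + 0.1 (j-1))` (or
exponentially, rate 0.07) in the treatment group only, giving interior
power at the default sample size. Features are drawn independently, so
the simulator does not emulate cross-taxon compositional coupling,
sequencing-depth variation, or overdispersion beyond zero inflation —
passing tests demonstrate correctness of the estimator under its stated
moment model, not robustness to those real-data features (the
distribution-free construction addresses the latter analytically, not
empirically, here).

## Evaluation scales

The statistical checks in `tests/test_acceptance.py` and
`scripts/acceptance.py` run at reduced problem sizes chosen so each
experiment's Monte-Carlo error is small relative to its tolerance:
300-feature single-replicate studies for error rates, 100-300 replicates
for bias/calibration/efficiency, 1e5 draws for marginal checks. These are
the package's own evaluation sizes; all conclusions are at the design's
per-condition sample sizes (n = 25, M = 10).

## Known limitations

Unbalanced panels are not modelled (subjects with incomplete series are
dropped on read); no ZINB-margin likelihoods or covariate-dependent
dispersion; no m-dependent or unstructured working correlations; no
cross-component within-time working correlation (fixed `I2`), although the
true `f1`/`f2` correlation at a time point is strongly negative — a known
efficiency (not validity) loss of the block structure; small-sample
sandwich corrections are not applied, so raw type-I error runs slightly
above nominal at small N (observed ~0.07 at n = 25 per group).
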