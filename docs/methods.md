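# Methods

## Model

The observation unit is a crash with a binary severity outcome (fatal /
non-fatal). The latent-utility formulation — utility linear in covariates
plus a logistic residual, fatal iff positive — is kept as the generative and
documentation view; all inference uses the equivalent Bernoulli-logistic
likelihood, which is numerically simpler and identical in content.

Three nested families:

1. **logistic**: p₁ = expit(β₀ + Σⱼ βⱼ xⱼ);
2. **spatial logistic**: adds a section effect φₘ to the predictor. Sections
   are stretches of freeway homogeneous in horizontal curvature and vertical
   grade; first-order adjacency (sharing a common end) makes a single freeway
   a chain graph, though the builder accepts arbitrary edge lists. φ carries
   a Leroux CAR prior with conditional mean
   ρ Σ ωφ / (1 − ρ + ρ Σ ω) and conditional variance δ² / (1 − ρ + ρ Σ ω).
   For ρ < 1 the joint is a proper Gaussian with precision
   Q = (ρ(D − W) + (1 − ρ)I)/δ². ρ = 1 (intrinsic CAR) leaves the joint
   improper; it is admitted only in conditional updates, never in joint
   density evaluation, and the U(0, 1) prior makes the boundary measure-zero;
3. **random-parameters spatial logistic**: crash-level coefficients
   βᵢⱼ = β̄ⱼ + μᵢⱼ, μᵢⱼ ~ N(0, σⱼ²), for a chosen random set (default: the
   Truck indicator). Deviations are crash-level as specified, not
   section-level; identification then rests entirely on the normal mixing
   prior (see "Weak identification" below).

Priors (the reference protocol): N(0, 10⁴) — variance 10⁴, SD 100 — on β, β̄;
U(0, 1) on ρ; U(0.01, 10) on δ and every σⱼ.

## Sampler

Metropolis-within-Gibbs with adaptive random-walk kernels:

* scalar coefficients: one-at-a-time Gaussian random walks on a cached linear
  predictor (each update costs one O(N) likelihood evaluation);
* crash-level deviations μ: a vectorized independent-Metropolis sweep —
  each crash's deviation touches only its own Bernoulli term. Deviations are
  instantiated only where the covariate is non-zero; for x = 0 the product
  μ·x vanishes from the likelihood, so dropping those latents is exact
  marginalization, not an approximation;
* section effects φ: vectorized sweeps over graph-coloring classes (no two
  adjacent sections update together), with the Leroux conditional as prior
  and per-section likelihood contributions aggregated by bincount;
* ρ on the logit scale with Jacobian, using the joint CAR density through the
  precomputed Laplacian eigenvalues (log det Q = Σ log(ρλₖ + 1 − ρ) − 2M log δ);
* δ and σⱼ: random walks on the log scale truncated to (0.01, 10), each
  followed by an ancillarity–sufficiency interweaving move (a non-centered
  rescale of the scale together with its latents). The interweaving move has
  the same invariant distribution and is needed because a scale conditioned
  on hundreds of latents otherwise moves in ~1/√(2n) relative steps.

Proposal scales adapt by Robbins–Monro toward 0.44 acceptance during burn-in
only, so the retained chain is a fixed-kernel Markov chain. Initialization:
coefficients 0, φ = 0, ρ = 0.5, δ = σ = 1. Default run length 100,000
iterations, 50,000 burn-in, one chain. Convergence is flagged per parameter
by the batch-means rule (50 batches): MC error / posterior SD strictly below
5%; constant chains are flagged indeterminate rather than passed.

The sampler was validated against independent oracles: the statsmodels MLE
for the plain logistic; the closed-form flat-prior posterior of the
intercept-only model (logit of a Beta law); a Gauss–Hermite marginalization
of the deviations in a reduced random-parameters model; prior moments under
prior-only sampling; and the inverse Leroux precision for prior-only φ draws.

### Random-to-fixed collapse rule

A positive-support SD can never have an interval bracketing zero, so "the
posterior variance is not significant" is operationalized as: the 2.5th
posterior percentile of σ lies below twice the prior's lower bound (0.02).
`fit_model` refits with the covariate moved to the fixed set when the rule
triggers. The rule's mechanics are tested; note, however, that on synthetic
null data (σ = 0) the σ posterior is typically diffuse over (0.05, ≈2.5)
rather than piled at the boundary, so the rule rarely triggers there — the
criterion detects a boundary-degenerate posterior, not the absence of
heterogeneity. A ΔDIC refit comparison is the more informative alternative.

## Weak identification of crash-level random parameters

A binary-outcome model with a per-observation random coefficient and diffuse
priors has a degenerate ridge: letting β̄ → −kσ with σ large makes every
affected crash's marginal fatality probability a constant Φ(−k), fitted to
the group's observed fatality rate, while each crash's own deviation can
absorb its outcome. At the study's event counts (tens of fatal crashes) this
ridge carries substantial posterior mass — it gains both marginal likelihood
(in-sample) and an enormous prior volume relative to the narrow
data-coherent region. Long, well-mixed chains therefore sometimes leave the
neighborhood of the generative parameters and settle at large σ with all
scales inflated; shorter chains started at the default initial values often
remain in the data-coherent basin. The package does not hide this: recovery
experiments report honest coverage, and the phenomenon is visible in the
`fit_and_compare` example at small N. Consequences worth knowing:

* credible intervals for β̄, σ (and, through section-effect inflation, δ) can
  fail to cover the generative values in a minority of replicates;
* conditional DIC (see below) can reward the ridge's in-sample fit even on
  data generated without heterogeneity, occasionally separating the
  random-parameters family from the others by more than 10;
* weakly informative priors on σ or group-level (rather than crash-level)
  random parameters remove the ridge, but both depart from the reference
  protocol, so neither is the default here.

## Reporting

Equal-tailed credible intervals at 90/95%; a coefficient is significant at a
level when its interval excludes zero. Odds ratios exp(β) with percent form
100(exp(β) − 1); full precision is kept, rounding is left to the formatting
layer. The heterogeneity share is 100·Φ(β̄/σ), invariant to rescaling
(β̄, σ) → (cβ̄, cσ).

**DIC** is the conditional (focused) form: the deviance conditions on the
sampled φ and crash-level coefficients; D̄ is the mean deviance over kept
draws and D(θ̂) is evaluated at the posterior mean of all focus parameters.
Because the predictor is linear in those parameters, the predictor at the
posterior mean equals the posterior-mean predictor, which the sampler tracks
exactly; pD = D̄ − D(θ̂) and DIC = D̄ + pD hold by construction. A marginal
DIC is out of scope. Models are ranked by DIC with a strict ΔDIC > 10
decisive-superiority flag.

**Average marginal effects** integrate over the posterior by default
(a plug-in-at-posterior-means option exists). Posterior averaging uses an
evenly thinned subsample of draws (at most 500) for which the crash-level
deviations are stored alongside the scalar draws; the AME of a Δx change in
a continuous covariate is the mean over crashes and draws of
p₁(x + Δx) − p₁(x) at observed values of everything else. Indicator
covariates are rejected (their effect is the odds ratio).

## Synthetic-data generator

The generator defines the study conditions: N = 1414 crashes on an
M = 154-section chain, covariates drawn independently at the published
marginals, φ drawn jointly from the proper Leroux CAR (Cholesky of Q), Truck
deviations drawn N(0, σ²) per crash, outcomes Bernoulli-logistic. Defaults
for the truth are the published random-parameters posterior means
(β₀ = −7.10, EMS 0.026, Truck 0.51 with σ = 1.23, ρ = 0.68, δ = 0.56, …).

Marginal families, moment-matched so the *truncated* mean and SD equal the
published values:

* EMS response time, visibility, precipitation: truncated log-normal (long
  right tails; EMS bounded to [1, 260] minutes);
* grade, wind speed, temperature, humidity: truncated normal with the
  location/scale solved numerically;
* curvature: scaled Beta on [0, 4.35] — a truncated normal on that box
  cannot reach SD 1.233 at mean 1.838 (its supremum is ≈1.229), and the Beta
  solution also concentrates mass at zero curvature (straight sections);
* indicator groups (vehicle type, time of day, crash type): categorical at
  the published member shares with the reference level taking the remainder.
  The raw vehicle categories overlap ("at least a truck…"), so their printed
  shares sum to 1.054; drawing the non-reference members at their exact
  shares reproduces every modeled indicator's mean, at the cost of the
  (unmodeled) reference share being 0.525 rather than 0.579.

What the generator does **not** emulate: covariate dependence (correlations
are zero, consistent with the reported absence of significant correlation),
real weather time series, km-resolved geometry, or per-section crash-count
patterns (assignment is uniform unless weights are given). One visible
consequence: at the published effect sizes with independent marginals the
generative fatality rate is ≈0.055–0.060, not the observed 0.025. The
dominant contribution is the precipitation tail — a coefficient of 0.95 per
mm with a marginal SD of 3.425 mm forces 1–2% of crashes into
near-saturated fatality probability regardless of the distributional family
(a two-point moment bound), something only covariate dependence in the real
data can avoid. The intercept-calibration helper (`target_rate=...`) solves
β₀ to hit any desired rate exactly (β₀ ≈ −9.7 for 2.5%); the intercept-only
experiments instead use the exact observed split (36 fatal of 1,414).
Passing recovery tests on these data therefore show correct inference under
the model's own assumptions, not fidelity to the unavailable real data.

## Problem sizes used in the simulation experiments

* parameter recovery: 10 replicates at N = 1414, M = 154, fitted with 20,000
  iterations / 10,000 burn-in each;
* DIC family ordering: 5 heterogeneous-truth and 5 null-truth replicates at
  full size, each family fitted with 8,000 / 4,000 — chain lengths chosen so
  the whole study runs in minutes while the DIC ranking is stable;
* intercept-only check: 20,000 / 10,000 on the 36/1414 split;
* prior-recovery and CAR-covariance checks: 80,000–100,000 prior-only
  iterations on small networks.

The null scenario for the ordering study is the plain-logistic generative
limit (no section effects and no heterogeneity): with ρ = 0 but δ > 0 the
i.i.d. section effects would still be a real random effect that a spatial
model legitimately detects, which is not the hypothesis the null arm tests.

## Numerical choices and degenerate inputs

Likelihood terms use `-logaddexp(0, -sgn·η)`, stable to |η| ≈ 700; expit
saturates to exactly 0/1 beyond that, which the reporting layer tolerates.
Sections without crashes receive prior-conditional φ updates (their full
conditional reduces to the Leroux conditional). The segmentation tolerance
defaults to exact equality of curvature/grade, configurable; crashes map to
sections by half-open [start, end) intervals with the final end closed.
Constant chains yield an indeterminate (not passing) convergence flag.
Degenerate inputs — empty draws, non-binary outcomes, non-positive EMS
times, double-active indicator groups, asymmetric adjacency, self-edges,
ρ outside [0, 1], σ ≤ 0 — raise errors naming the offending element.

## Known limitations

* The weak-identification ridge above is a property of the specified model
  at realistic event counts; this package reports it rather than suppressing
  it, and single-chain results for σ, β̄ and δ should be interpreted with
  trace plots in hand.
* One chain by default (multi-chain runs are available via `n_chains`-style
  looping over seeds, but no Gelman–Rubin machinery is included).
* Conditional DIC is the only comparison criterion; WAIC/LOO are out of
  scope.
* The Pólya-Gamma augmentation path is not implemented; all updates are
  Metropolis-based.
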