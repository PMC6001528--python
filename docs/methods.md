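# Methods

## Model

The analysis scale is the contrast scale: each trial contributes its observed
treatment effects versus its own baseline arm (arm 1), assumed normal with
known within-study covariance. For trial *i*, arm *k* ≥ 2:

    y_ik ~ N(θ_ik, v_ik),    θ_ik = δ_ik + β_{t_i1, t_ik} · c_i

Basic parameters are the effects d₁ₜ and coefficients β₁ₜ of every treatment
versus the network reference; all other (functional) parameters follow from
the consistency relations d_{ab} = d_{1b} − d_{1a}, β_{ab} = β_{1b} − β_{1a}.
Interaction structures:

* **independent** — one free β₁ₜ per non-reference treatment; requires every
  basic coefficient to be identified (trials contributing to it must span at
  least two covariate values; the design build raises a named estimability
  error otherwise);
* **exchangeable** — β₁ₜ ~ N(B, υ²), realised as shrinkage pseudo-rows of the
  design system (response B, indicator design row, variance υ²). υ is fixed
  by the user; B is either fixed or estimated as a free column. Keeping υ
  fixed keeps the system linear given the variance components, which the
  contribution method requires;
* **common** — a single β; rows whose baseline arm is not the reference get
  an interaction entry of zero, because the functional coefficients are then
  identically zero.

Random-effects models give the trial-specific effects common between-trial
variance σ², with covariance σ²/2 between contrasts of the same multi-arm
trial (the standard homogeneous-variance convention that keeps the implied
arm-level model coherent). Fixed-effect models set σ² = 0.

## Estimation

Given the variance components everything is linear-Gaussian, so point
estimation is generalised least squares: θ̂ = (X′V⁻¹X)⁻¹X′V⁻¹y with
S = (X′V⁻¹X)⁻¹. Heterogeneity is estimated by REML — the profile of the
restricted likelihood is searched on the σ scale over [0, 10] by bounded
scalar minimisation (tolerance 1e−8 on σ), with an explicit boundary check so
σ̂² = 0 is attainable exactly. REML was chosen for the frequentist path
because it is the standard low-bias estimator in this class and pairs with
the variance-decomposition study weights, which are defined for frequentist
fits.

Normal priors enter as pseudo-rows of the design system (response = prior
mean, indicator design row, variance = prior variance). This makes the
fixed-effect Bayesian posterior available in closed form (augment + GLS) and
makes prior contributions fall out of the same linear-weight formula as data
contributions.

The Bayesian path is a Gibbs sampler on the *marginal* formulation: the
trial-specific effects δ are integrated out analytically, leaving
y ~ N(Xθ, V(σ)). θ is drawn jointly from its exact multivariate-normal full
conditional; σ takes a random-walk Metropolis step under its Uniform(0, 10)
prior, with the step size adapted toward a 35% acceptance rate during
burn-in only. Defaults mirror standard practice for this model family
(3 chains, 300 000 iterations, 100 000 burn-in, thinning 5); the test suite
and acceptance script use scaled-down chains (3 × 4000–6000), which this
low-dimensional conjugate-core sampler mixes through easily (split-chain
R̂ < 1.01 throughout; a warning is raised whenever any R̂ exceeds 1.05).
Marginalising δ means the reported DIC (D̄ + p_D, with D̂ evaluated at the
posterior means of θ and σ) is the marginal-likelihood DIC; samplers that
keep δ as latent variables report a conditional DIC that can differ by a
model-dependent offset. For a fixed-effect model with vague priors p_D
approaches the design rank, which the tests assert.

Interval conventions: 1.96·se Wald intervals for frequentist fits, 2.5/97.5
posterior percentiles otherwise.

## Contributions

For any result c′θ (an effect at the covariate centre, an effect at a chosen
covariate value, or a coefficient — functional comparisons built by
consistency), the GLS estimate is w′y with w′ = c′(X′V⁻¹X)⁻¹X′V⁻¹ over all
rows of the (possibly prior-augmented) system. The percentage contribution
of row *j* is 100·|wⱼ|/Σₖ|wₖ|.

Design choices made where the construction was genuinely open:

* **Absolute-weight normalisation.** Signed weights can be negative (indirect
  evidence entering with opposing sign); published contribution tables for
  this method print non-negative percentages, so |w| normalisation is the
  default. A `signed=True` flag reports signed weights on the same scale for
  diagnostic use.
* **Prior rows are normalised jointly with data rows**, so data plus prior
  contributions sum to 100 and the prior block is reported under its own
  labels. With the default vague N(0, 100000) priors the prior share is
  numerically negligible (≈ 1e−5 %), as it should be.
* **Random-effects contributions condition on a plugged σ²** (REML estimate
  or posterior median): the linear-weight identity requires fixed variance
  components.
* **Study-level aggregation sums a study's data-point percentages**; this is
  the locus of the method's difference from per-study variance-decomposition
  weights for multi-arm trials.
* **Bins** are half-open [lo, hi) with the final bin closed, labelled
  "lo–hi"; a covariate falling outside every bin is an error naming the
  offending studies, not a silent drop.

The variance-decomposition study weights (Riley et al.) are
100·[S Fᵢ S]ₚₚ/Sₚₚ, Fᵢ = Xᵢ′Vᵢ⁻¹Xᵢ. They are per study, frequentist-only
(prior rows raise an unsupported-configuration error), and functional
comparisons are handled by rebuilding the design with the comparison's
baseline as reference — valid only under independent interactions, whose
fits are invariant to the reference choice. Both methods collapse to
classical inverse-variance percentages in pairwise fixed-effect
meta-analysis (asserted in the tests). A documented, deliberately asserted
contrast: rescaling one study's rows (y → k·y, V → k²·V, design row → k·row
— an information-preserving transformation) changes the hat-matrix
contributions but not the variance-decomposition weights.

## Contrast construction

* Binary outcomes: log odds ratios versus arm 1; variance = sum of the four
  reciprocal cell counts; shared-baseline covariance = 1/a₁ + 1/(n₁ − a₁).
  Any zero cell triggers a Haldane–Anscombe continuity correction (default
  0.5 added to every cell of that study); a zero cell with correction 0 is a
  degenerate-cell error.
* Continuous outcomes: standardised mean differences using the SD pooled
  across all arms of the study; variance 1/n₁ + 1/nₖ + y²/(2N) and
  shared-baseline covariance 1/n₁ + yⱼyₖ/(2N) with N the study total; Hedges
  correction J = 1 − 3/(4·df − 1), df = N − #arms, applied by default (J on
  the effect, J² on the covariance block). These are the standard pooled-SD
  formulas; published SMD datasets derived with other covariance conventions
  should be supplied at contrast level if exact agreement matters.
* Covariate centring subtracts the mean (or a user value) and records the
  accumulated shift, so predictions and bins operate on the original scale.
  Studies with missing covariates are excluded with a logged warning.

## Synthetic data

The generator works on the contrast scale, matching the analysis model
exactly: y = d + β·c + study effect (covariance σ²/2·(I + J) within a trial)
+ sampling noise whose multi-arm covariance is u₀·J + diag(u), with per-arm
variance components u ~ Uniform(0.02, 0.15). Defaults — 3 treatments, 150
studies, 20% three-arm, d = (0.3, −0.2), β = (0.02, −0.01), σ² = 0.03, and a
gappy covariate mixture (half the trials at 2–7, half at 25–35) — emulate a
moderately informative network whose covariate distribution forces
interpolation, the situation the diagnostics exist for. A small arm-level
binomial simulator exercises the binary input path end to end.

What the generator does *not* emulate: publication-bias-shaped variance
distributions, covariate measurement error, inconsistency (the generating
model is consistent by construction), or non-normal sampling error in small
trials. Passing tests therefore demonstrate correctness of the estimation
and contribution machinery under the stated model, not robustness to those
real-data features.

Problem sizes used by the test suite and acceptance script — 200 replicates
of 150 studies for interval calibration, 100 replicates of 200 studies for
REML recovery, 3 × 4000–6000 Gibbs iterations — were chosen as the smallest
sizes at which the Monte-Carlo error of each check is comfortably below the
tolerance asserted for it.

## Known limitations

* Arm-level likelihoods (binomial logistic models) are out of scope; the
  normal approximation on the contrast scale is assumed throughout.
* No inconsistency (node-splitting) machinery and no missing-covariate
  imputation.
* Exchangeable-interaction fits fix υ rather than estimating it; estimating
  υ would require either a profile step in the frequentist path or an extra
  Metropolis step in the sampler, and the contribution formula would still
  condition on a plugged value.
* The marginal DIC differs from the conditional DIC of latent-variable
  samplers by a model-dependent offset; DIC comparisons are meaningful
  within this package, not across parameterisations.
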