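# Methods

## The inferential model

The response at each nest is the number of chicks fledged out of a
maximum brood of four, treated as Binomial(4, p). On the latent logit
scale the linear predictor decomposes lay date into a between-year part
(the annual mean, grand-mean centred) and a within-year part (each nest's
deviation from its year's mean), following the standard within-subject
centring argument: the between-year coefficient measures how population
mean success tracks population mean timing, while the within-year linear
and quadratic coefficients measure directional and stabilising selection
on relative timing. Year-level random intercepts and relative-date slopes
carry an unstructured covariance, so both average success and the
steepness of within-year selection may vary among years.

Two structural choices mirror the standard animal-model treatment of
binomial traits:

* a latent Gaussian residual with **variance fixed at 1** sits beneath the
  binomial link (overdispersion absorbed on the latent scale; fixing the
  variance is required for identifiability);
* all coefficients are reported on that latent logit scale. For
  data-scale predictions the linear predictor is shrunk by
  `1/sqrt(1 + c² σ²_e)` with `c² = (16√3/(15π))²` before the logistic
  map — the usual logistic-scaling correction.

Covariate variants add, per the model roster: centred calendar year and
its interaction with relative date (year model); centred current or
previous-year late-winter SST plus centred year and the SST×relative-date
interaction (SST models); or centred log breeding-pair count (population
model). Relative timing always stays centred within year, so variant
covariates never contaminate the selection terms.

The diet response is the offset-logit of the 1+ group sandeel biomass
proportion, `ln((p+0.01)/(1−p+0.01))`, modelled as Gaussian with the same
year-level random-regression structure and an estimated residual
variance. The bivariate model stacks both traits with a 4×4 year-level
covariance over (B_Sh, B_Sa, W_Sh, W_Sa); relative timing for *both*
traits is centred on the annual mean lay date so that the cross-trait
covariances address the mismatch predictions directly. The quadratic term
applies to the breeding-success trait only. Years present in only one
table are retained and inform their own trait, linked through the
covariance; diet-only years are centred on a supplied mean lay date when
available, else their own mean sample date (logged).

## Sampler

A Gibbs scheme targets the exact posterior:

1. **Latent values** (binomial rows): the full conditional factorises by
   observation, `p(l | y, η) ∝ Binom(y | 4, logistic(l)) N(l | η, 1)`;
   a random-walk Metropolis step with a globally adapted step size
   (adaptation frozen after burn-in) updates all latents in one pass.
2. **Fixed and random effects jointly** from their Gaussian full
   conditional — a single multivariate draw, so the sampler does not
   suffer the slow mixing of alternating fixed/random updates.
3. **Parameter expansion**: random effects are parameterised as
   `u_i = diag(α) v_i` with `v_i ~ N(0, Ψ)`, `Ψ ~ InvWishart(q, I_q)` and
   working scales `α ~ N(0, 25² I)`. α has a conjugate Gaussian update
   (it enters the likelihood linearly given v), Ψ a conjugate
   inverse-Wishart update. The reported covariance `Σ = diag(α) Ψ diag(α)`
   then carries a heavy-tailed scaled-F-type marginal prior that mixes
   well when variance components sit near zero.
4. **Gaussian residual variance** (diet rows) from a conjugate
   inverse-gamma update with a weak proper prior (ν = 0.002, V = 1).

Fixed effects get independent N(0, 10⁸) priors by default (configurable
per column — the calibration tests use proper moderate priors).
Significance is reported exclusively as "95% credible interval excludes
zero"; no p-values are attached to Bayesian fits.

Default chain lengths are 100,000 iterations (400,000 bivariate) with
10% burn-in and thinning 10; a `fast` profile (10,000 iterations) exists
for tests and is flagged `reduced_scale` in the output metadata.
Effective sample sizes are computed per parameter; any fixed effect
below 100 triggers a recorded (non-fatal) convergence warning.

Numerical safeguards: all Cholesky factorisations fall back to an
escalating diagonal jitter (degenerate inputs such as exactly constant
responses otherwise produce numerically indefinite precision matrices),
the covariance update always draws the full matrix (every stored draw is
positive semi-definite by construction), and the Gaussian residual
variance is floored at 1e−10.

Validation: the test suite runs simulation-based calibration (200
replicates on a 10-year × 30-nest design, χ² rank-uniformity at
α = 0.01 for μ, β_W, γ and σ²_int), a short-vs-10×-longer chain
comparison, null-data coverage, and replicated parameter-recovery
coverage of the core model.

## Derived statistics

* **Vertex** `v = −β_W/(2γ)` computed per draw and then summarised; the
  posterior mean of the ratio is *not* the ratio of posterior means
  (with constant draws β_W = −0.026, γ = −0.0007 the vertex is −18.571;
  a full posterior typically summarises a few days away from that
  plug-in value). Draws with γ exactly 0 are excluded and counted; more
  than 5% exclusions raises a warning.
* **Optimum sensitivity** `B = dx̄/dE − β_int/(2γ)`: the absolute optimum
  in environment E is the annual mean timing plus the within-year vertex,
  so its derivative combines the fixed mean-timing trend slope with the
  per-draw interaction/quadratic ratio. The point estimate uses the trend
  slope exactly (with a zero interaction posterior B equals the timing
  trend); the CI adds the trend slope's sampling SE to the posterior
  draws in quadrature on the draw scale.
* **Trend fits**: GLS with AR(1) errors; the error correlation between
  observations at years t₁, t₂ is φ^|t₁−t₂| — calendar years, not row
  indices, so gap years lengthen the lag. φ is profiled by maximum
  likelihood (bounded at |φ| ≤ 0.98, with an exact-OLS shortcut when the
  profile prefers φ = 0); two-sided p-values use t with n − 2 df, which
  the ± values reported alongside slopes treat as standard errors.

## Synthetic-data generator

The generator emulates the study design, with defaults frozen to the
study conditions: 30 years from 1987 with 1993 and 2003 missing, 35–266
nests per year, SST mean 5.94 °C with trend 0.02 °C/yr, AR(1) φ = 0.27
and innovation SD 0.35 °C; annual mean lay date intercept at day 127
with trend −0.94 days/yr, SST response −6.30 days/°C, annual noise SD 5
days and within-year nest spread SD 12 days (calibrated to the overall
observed lay-date span for this system, days 71–217; no direct
within-year variance estimate exists to copy); latent fledging model
μ = −0.9, β_B = −0.035, β_W = −0.026,
γ = −0.0007, σ²_int = 0.3, σ²_slope = 1e−4; diet within-season slope
−0.095 logit/day with among-year variances 6.46 (intercepts) and 0.015
(slopes); cross-trait year effects drawn jointly from a 4×4 covariance
with σ(B_Sh,B_Sa) = −0.363 and σ(W_Sh,W_Sa) = 0.0003 as defaults,
matching the field estimates for this system. Because the direct year
trend and the
SST-mediated path both act on lay date, the realised marginal lay-date
trend under the defaults is ≈ −1.07 days/yr.

Free parameters without a field estimate to copy, chosen once as
realistic for this system: within-year lay-date spread is Gaussian (matching the
symmetric-spread assumption implicit in centring); gap years are dropped
*after* generation so year remains a continuous covariate; diet sample
dates are Normal(annual mean lay date + 40, SD 10), truncated to the
chick-rearing season (days 90–212), which reproduces the strong
collection-date/lay-date correlation; the diet latent intercept is 0.5
(mean proportion ≈ 0.62 at the mean collection date) with residual SD
0.8; annual breeding-pair counts are lognormal.

What the generator does **not** emulate, hence what passing tests do not
show about real data: no nest-site or plot structure, no individual
identity across years, no replacement clutches, no measurement error in
lay date (up to 4 days in the field protocol), and proportions are
generated by clipping the inverse offset-logit to [0, 1]. That clipping
matters: boundary proportions (all-1+ or no-1+ samples) are *censored*
observations that the Gaussian diet model treats as exact, so with the
large default among-year intercept variance (6.46 logit²) whole years
sit at the boundary and intercept-variance recovery is attenuated by
roughly 20%. This is a property of the observation process, not of the
sampler; recovery and calibration tests therefore target the slope and
covariance parameters, where the model is well-specified, and the
attenuation is documented rather than hidden.

## Problem sizes used by tests and the acceptance script

Replicated checks run at reduced scale, chosen to keep the whole suite in
a few minutes while leaving each check well-powered: core-model recovery
at 30 years × 150 nests with the 10k-iteration fast profile (50
replicates); vertex calibration at 15 years × 60 nests (50 replicates);
simulation-based calibration at 10 years × 30 nests (200 replicates);
bivariate null at 12 years × 40 nests (30 replicates).
`scripts/acceptance.py` runs the full default study frame (30 years,
35–266 nests/year, ~1100 diet samples) with 30k-iteration univariate and
60k-iteration bivariate chains.

## Known limitations

* The Metropolis latent step is the mixing bottleneck at very large nest
  counts; effective sample sizes per iteration are lower than a
  slice-sampling latent update would give.
* φ in the GLS trend model is noticeably biased low at n ≈ 30 (a
  well-known property of ML AR(1) estimation); the slope itself is
  unbiased, which is what the recovery checks assert.
* The SST-based optimum sensitivity inherits the large sampling noise of
  the lay-date-on-SST regression (one 30-year realisation); its CI is
  wide by construction.
* No Poisson-family robustness refits, no replacement-clutch analysis,
  no information-criterion model comparison — out of scope by design.
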