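# phenomatch

Statistical pipeline for detecting **fitness signatures of phenological
mismatch** in long-term breeding studies, built around the European shag
(*Gulosus aristotelis*) / lesser sandeel (*Ammodytes marinus*) system: does
a consumer's breeding success fall when its timing desynchronises from the
seasonal availability of its principal prey?

The package is aimed at population ecologists who have nest-level breeding
records, annual environmental covariates and colony-level diet samples,
and want to ask the match–mismatch question with random-regression mixed
models rather than with annual means alone.

## The models

**Breeding success.** Each nest fledges *n* of a maximum brood of 4
chicks. The core model is a Bayesian binomial-logit GLMM with
within-year centring of lay date,

```
logit p_ij = μ + u_i + β_B x̄_i + (β_W + w_i)(x_ij − x̄_i)
             + γ (x_ij − x̄_i)² + e_ij ,     n_ij ~ Binomial(4, p_ij)
```

where `x̄_i` is year *i*'s mean lay date, `β_B` the *between-year*
(population, BSp) slope, `β_W` the *within-year* (individual, BSi)
directional-selection slope, `γ` the quadratic (stabilising-selection)
term, `(u_i, w_i)` year-level random intercepts and slopes with an
unstructured 2×2 covariance, and `e_ij` a latent residual with variance
fixed at 1. Covariate variants add year, current/previous late-winter SST,
or log population size, each with its interaction with relative lay date.

Derived statistics, all computed draw-by-draw from the posterior:

* **vertex** `−β_W/2γ` — the relative lay date where expected fitness
  peaks (negative = days before the annual mean);
* **among-year slope variance** `σ²_W` — does the strength of selection
  vary between years?
* **B** — the advance rate of the *absolute* optimum lay date per unit of
  environment (days/year or days/°C), combining the mean-timing trend with
  the posterior shift of the relative optimum,
  `B = dx̄/dE − β_int/2γ`.

**Diet seasonality.** The biomass proportion of 1+ group (older, more
profitable) sandeels among all sandeels in each regurgitate is mapped
through an offset logit, `ln((p + 0.01)/(1 − p + 0.01))`, and modelled as
Gaussian with year-level random intercepts and within-season slopes.

**Bivariate model.** Breeding success (binomial) and diet proportion
(Gaussian) fitted jointly, both centred on the annual mean lay date, with
a 4×4 year-level covariance over (B_Sh, B_Sa, W_Sh, W_Sa). Mismatch
predicts positive covariances `σ(B_Sa, B_Sh)` and `σ(W_Sa, W_Sh)`.

**Trends.** Annual series (SST, mean lay date) are fitted by GLS with
AR(1) errors, profiling the autocorrelation φ by maximum likelihood, with
calendar-year lags so gap years widen the lag rather than disappearing.

The sampler is a purpose-built Gibbs scheme (Metropolis latent updates,
conjugate joint fixed/random-effect draws, parameter-expanded
inverse-Wishart covariance updates) with the inner loop compiled by numba;
its calibration is verified by simulation-based calibration in the test
suite.

A **synthetic-data generator** reproduces the whole study design — AR(1)
SST, advancing lay dates, binomial fledging with year-level random
regression, seasonal diet decline, cross-trait year effects — so every
stage of the pipeline is testable without the original data, and ships a
ground-truth record for parameter-recovery checks.

## Worked example

```python
from phenomatch import (SimulationParams, simulate_dataset, build_design,
                        ModelSpec, MCMCSettings, fit_model, summarize,
                        vertex)

data = simulate_dataset(SimulationParams(nests_per_year=(150, 150)), seed=7)
design = build_design(data["breeding"], None, ModelSpec("core"))
post = fit_model(design, MCMCSettings.fast(seed=3))   # 10k iterations
print(summarize(post)[["parameter", "mean", "ci_low", "ci_high"]])
v = vertex(post)
print(f"fitness peak {v.mean:.1f} days relative to the annual mean "
      f"[{v.ci_low:.1f}, {v.ci_high:.1f}]")
```

Output (seeds as above):

```
                            parameter      mean        ci_low   ci_high
0                           intercept -1.047949 -1.307195e+00 -0.804174
1                        mean_laydate -0.020526 -4.319358e-02  0.001288
2                         rel_laydate -0.027408 -3.272457e-02 -0.022484
3                      rel_laydate_sq -0.000705 -9.875279e-04 -0.000431
4                 var(year_intercept)  0.495459  2.605084e-01  0.887938
5  cov(year_intercept,year_rel_slope) -0.000250 -4.372635e-03  0.003695
6                 var(year_rel_slope)  0.000063  9.275321e-08  0.000220
fitness peak -20.3 days relative to the annual mean [-31.8, -13.5]
```

Nests laying later than their year's mean fledge fewer chicks
(`rel_laydate` < 0), the significant negative quadratic term indicates
stabilising selection, and the fitted fitness peak sits about three weeks
before the annual mean lay date — early, but not earliest, breeders do
best (the generating values were β_W = −0.026, γ = −0.0007).

The same models run from the shell:

```bash
phenomatch simulate --seed 1 --out data/
phenomatch trends --env data/env.csv --breeding data/breeding.csv
phenomatch fit --model core --breeding data/breeding.csv --fast --out out/
phenomatch report --simulate --seed 1 --fast --out report/
```

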