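"""Synthetic colony generator.

Produces breeding, environment and diet tables with the statistical
structure the downstream models assume: an AR(1) SST series with a linear
trend, annual mean lay dates responding to year and SST, nest-level
fledging counts from a latent-logit binomial with year-level random
intercepts and relative-lay-date slopes, and colony diet samples whose
older-sandeel proportion declines within each season.  Year-level random
effects for the two traits are drawn jointly from a 4x4 covariance matrix
so cross-trait (mismatch) couplings can be simulated and recovered.

All outputs are plain pandas DataFrames; dates are integer ordinal days
(January 1st = 0).  Every function is deterministic given ``(params, seed)``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
from scipy.special import expit

from .params import CROSS_COV_ORDER, GroundTruth, SimulationParams
from .transforms import inv_logit_offset

# diet samples are collected during chick rearing, April-July
SEASON_FIRST_DAY = 90
SEASON_LAST_DAY = 212


def simulate_sst(params: SimulationParams, seed: int) -> pd.DataFrame:
    """Simulate the late-winter SST series.

    Returns one row per simulated calendar year (gap years included, since
    the environment exists in years without nest monitoring) with columns
    ``year``, ``sst`` and ``sst_prev``; ``sst_prev`` is the realised value
    for the preceding calendar year, with the pre-study year drawn from the
    stationary AR(1) distribution around its trend value.
    """
    phi = params.sst_ar_phi
    if abs(phi) >= 1.0:
        raise ValueError(f"AR(1) coefficient must satisfy |phi| < 1, got {phi}")
    rng = np.random.default_rng(seed)
    years = params.year_range()
    # generate one extra leading year so the first lag is a realised value
    all_years = np.arange(years[0] - 1, years[-1] + 1)
    year_c = all_years - years.mean()
    trend = params.sst_mean + params.sst_trend * year_c

    n = all_years.size
    noise = np.empty(n)
    stat_sd = params.sst_sd / np.sqrt(1.0 - phi**2)
    noise[0] = rng.normal(0.0, stat_sd) if params.sst_sd > 0 else 0.0
    innov = rng.normal(0.0, params.sst_sd, size=n - 1) if params.sst_sd > 0 \
        else np.zeros(n - 1)
    for t in range(1, n):
        noise[t] = phi * noise[t - 1] + innov[t - 1]
    series = trend + noise
    return pd.DataFrame({
        "year": years,
        "sst": series[1:],
        "sst_prev": series[:-1],
    })


def simulate_phenology(params: SimulationParams, sst: pd.DataFrame,
                       seed: int) -> pd.DataFrame:
    """Simulate nest-level lay dates for each retained year.

    The annual mean lay date follows a linear year trend plus an SST
    response (relative to the mean SST of the simulated period) and annual
    noise; nests scatter around it with a Gaussian spread.  Gap years are
    dropped from the output.
    """
    years = params.kept_years()
    if years.size == 0:
        raise ValueError("no years remain after dropping gap years")
    sst_map = sst.set_index("year")["sst"]
    missing = [int(y) for y in years if y not in sst_map.index]
    if missing:
        raise ValueError(f"SST series lacks simulated years: {missing}")

    rng = np.random.default_rng(seed)
    year_c = years - params.year_range().mean()
    sst_dev = sst_map.loc[years].to_numpy() - sst["sst"].mean()
    annual_mean = (params.laydate_intercept
                   + params.laydate_trend * year_c
                   + params.laydate_sst_slope * sst_dev
                   + rng.normal(0.0, params.laydate_year_sd, size=years.size))

    lo, hi = params.nests_per_year
    n_nests = rng.integers(lo, hi + 1, size=years.size)
    rows = []
    for y, mean_day, n in zip(years, annual_mean, n_nests):
        dates = np.rint(mean_day + rng.normal(
            0.0, params.laydate_within_sd, size=n)).astype(int)
        rows.append(pd.DataFrame({
            "year": y,
            "nest_id": [f"{y}-{k:03d}" for k in range(n)],
            "lay_date": dates,
        }))
    return pd.concat(rows, ignore_index=True)


def draw_year_effects(params: SimulationParams, years: np.ndarray,
                      seed: int) -> np.ndarray:
    """Draw the joint (B_Sh, B_Sa, W_Sh, W_Sa) year effects, one row per year."""
    cov = params.effective_cross_cov()
    rng = np.random.default_rng(seed)
    # eigh-based root: tolerant of semi-definite matrices (zero variances)
    w, v = np.linalg.eigh(cov)
    root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((len(years), 4))
    return z @ root.T


def simulate_breeding(phenology: pd.DataFrame, params: SimulationParams,
                      seed: int, sst: Optional[pd.DataFrame] = None,
                      year_effects: Optional[np.ndarray] = None,
                      ) -> pd.DataFrame:
    """Simulate fledging counts for each nest in the phenology table.

    The latent logit is mu + u_i + beta_B * (annual mean lay date, grand
    centred) + (beta_W + w_i + interactions) * relative lay date
    + gamma * relative lay date^2 + unit-variance-style residual noise, and
    the fledged count is Binomial(4, logistic(latent)).  ``u_i`` and ``w_i``
    are the B_Sh / W_Sh components of the year effects, drawn jointly with
    the diet components unless supplied.
    """
    rng = np.random.default_rng(seed)
    years = np.sort(phenology["year"].unique())
    if year_effects is None:
        year_effects = draw_year_effects(
            params, years, rng.integers(0, 2**31 - 1))
    year_effects = np.asarray(year_effects, dtype=float)
    if year_effects.shape != (years.size, 4):
        raise ValueError("year_effects must have one 4-vector per year")

    df = phenology.copy()
    year_mean = df.groupby("year")["lay_date"].transform("mean")
    rel = df["lay_date"] - year_mean
    grand_mean = df.groupby("year")["lay_date"].mean().mean()
    xbar_c = year_mean - grand_mean

    year_index = pd.Series(np.arange(years.size), index=years)
    idx = year_index.loc[df["year"]].to_numpy()
    u = year_effects[idx, CROSS_COV_ORDER.index("B_Sh")]
    w = year_effects[idx, CROSS_COV_ORDER.index("W_Sh")]

    year_c = df["year"].to_numpy() - params.year_range().mean()
    slope = params.beta_W + w + params.beta_W_year * year_c
    if params.beta_W_sst != 0.0:
        if sst is None:
            raise ValueError("beta_W_sst != 0 requires the SST series")
        sst_map = sst.set_index("year")["sst"]
        sst_c = sst_map.loc[df["year"]].to_numpy() - sst["sst"].mean()
        slope = slope + params.beta_W_sst * sst_c

    eta = (params.mu + u + params.beta_B * xbar_c
           + slope * rel + params.gamma * rel**2
           + rng.normal(0.0, params.resid_sd, size=len(df)))
    df["n_fledged"] = rng.binomial(4, expit(eta))
    return df[["year", "nest_id", "lay_date", "n_fledged"]]


def simulate_diet(phenology: pd.DataFrame, params: SimulationParams,
                  seed: int, year_effects: Optional[np.ndarray] = None,
                  ) -> pd.DataFrame:
    """Simulate regurgitate samples: (year, sample_date, prop_oneplus).

    Sample dates are Gaussian around the annual mean lay date plus a fixed
    collection offset, truncated to the chick-rearing season, so that median
    collection date tracks median lay date across years.  The latent
    offset-logit proportion declines linearly with relative sample date,
    with year-varying intercepts (B_Sa) and slopes (W_Sa).
    """
    rng = np.random.default_rng(seed)
    years = np.sort(phenology["year"].unique())
    if year_effects is None:
        year_effects = draw_year_effects(
            params, years, rng.integers(0, 2**31 - 1))
    year_effects = np.asarray(year_effects, dtype=float)

    annual_mean_lay = phenology.groupby("year")["lay_date"].mean()
    lo, hi = params.samples_per_year
    n_samples = rng.integers(lo, hi + 1, size=years.size)

    rows = []
    for k, (y, n) in enumerate(zip(years, n_samples)):
        centre = annual_mean_lay.loc[y] + params.diet_date_offset
        dates = np.rint(centre + rng.normal(
            0.0, params.diet_date_sd, size=n)).astype(int)
        dates = np.clip(dates, SEASON_FIRST_DAY, SEASON_LAST_DAY)
        rel = dates - dates.mean()
        v = year_effects[k, CROSS_COV_ORDER.index("B_Sa")]
        s = year_effects[k, CROSS_COV_ORDER.index("W_Sa")]
        latent = (params.diet_mu + v
                  + (params.diet_within_slope + s) * rel
                  + rng.normal(0.0, params.diet_resid_sd, size=n))
        rows.append(pd.DataFrame({
            "year": y,
            "sample_date": dates,
            "prop_oneplus": inv_logit_offset(latent),
        }))
    return pd.concat(rows, ignore_index=True)


def simulate_population_size(params: SimulationParams, seed: int,
                             log_mean: float = 7.0, log_sd: float = 0.25,
                             ) -> pd.DataFrame:
    """Simulate annual breeding-pair counts (lognormal year-to-year variation)."""
    rng = np.random.default_rng(seed)
    years = params.year_range()
    counts = np.rint(np.exp(rng.normal(log_mean, log_sd, size=years.size)))
    return pd.DataFrame({"year": years, "population_size": counts.astype(int)})


def simulate_dataset(params: SimulationParams, seed: int,
                     outdir: Optional[str] = None) -> dict:
    """Generate the full linked dataset and its ground-truth record.

    Returns a dict with keys ``breeding``, ``env``, ``diet`` (DataFrames)
    and ``truth`` (:class:`~phenomatch.params.GroundTruth`).  If ``outdir``
    is given, writes ``breeding.csv``, ``env.csv``, ``diet.csv`` and
    ``truth.json`` there.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s) for s in ss.generate_state(5) % (2**31 - 1)]

    sst = simulate_sst(params, seeds[0])
    phen = simulate_phenology(params, sst, seeds[1])
    years = np.sort(phen["year"].unique())
    effects = draw_year_effects(params, years, seeds[2])
    breeding = simulate_breeding(phen, params, seeds[3], sst=sst,
                                 year_effects=effects)
    diet = simulate_diet(phen, params, seeds[4], year_effects=effects)
    pop = simulate_population_size(params, seeds[2])

    env = sst.merge(pop, on="year")
    env = env[env["year"].isin(years)].reset_index(drop=True)

    truth = GroundTruth(params=params, seed=seed, year_effects=effects,
                        years=[int(y) for y in years])
    out = {"breeding": breeding, "env": env, "diet": diet, "truth": truth}

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        breeding.to_csv(outdir / "breeding.csv", index=False)
        env.to_csv(outdir / "env.csv", index=False)
        diet.to_csv(outdir / "diet.csv", index=False)
        truth.to_json(outdir / "truth.json")
    return out
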