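"""Model-matrix construction with between/within-year decomposition.

Every model decomposes a date covariate into its annual mean (a between-
year effect) and each observation's deviation from that mean (a within-
year effect).  The within-year centring is exact by construction — the
annual mean is the empirical mean of the rows entering the model — so the
between- and within-year coefficients are orthogonal by design.  Annual
means, calendar year and SST are grand-mean centred; population size
enters as a centred natural log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd

MAX_BROOD = 4

PHENOLOGY_VARIANTS = ("core", "core_popsize", "year", "sst_current",
                      "sst_previous")
DIET_VARIANTS = ("sandeel_core", "sandeel_year")


@dataclass
class ModelSpec:
    """Which fixed-effect roster to fit for the breeding-success model."""

    variant: str = "core"
    include_quadratic: bool = True

    def __post_init__(self) -> None:
        if self.variant not in PHENOLOGY_VARIANTS:
            raise ValueError(
                f"unknown variant {self.variant!r}; "
                f"choose from {PHENOLOGY_VARIANTS}")


@dataclass
class ModelDesign:
    """A ready-to-sample mixed-model layout.

    ``X`` holds the fixed effects, ``U`` the per-observation covariates of
    the year-level random effects (columns ordered as ``re_names``), and
    ``year_idx`` maps each row to its year's random-effect block.  Rows are
    binomial (successes out of ``trials``) or Gaussian according to
    ``family``.
    """

    X: np.ndarray
    colnames: List[str]
    U: np.ndarray
    re_names: List[str]
    year_idx: np.ndarray
    years: np.ndarray
    family: np.ndarray          # 'binomial' or 'gaussian' per row
    y: np.ndarray               # successes (binomial) or response (gaussian)
    trials: np.ndarray
    meta: Dict = field(default_factory=dict)

    @property
    def n_obs(self) -> int:
        return self.X.shape[0]

    @property
    def n_years(self) -> int:
        return self.years.size


def _validate_breeding(breeding: pd.DataFrame) -> pd.DataFrame:
    required = {"year", "nest_id", "lay_date", "n_fledged"}
    missing = required - set(breeding.columns)
    if missing:
        raise ValueError(f"breeding table lacks columns: {sorted(missing)}")
    bad = breeding.index[(breeding["n_fledged"] < 0)
                         | (breeding["n_fledged"] > MAX_BROOD)]
    if len(bad):
        raise ValueError(
            f"n_fledged outside 0..{MAX_BROOD} at rows {bad.tolist()}")
    return breeding


def build_design(breeding: pd.DataFrame, context: Optional[pd.DataFrame],
                 spec: ModelSpec) -> ModelDesign:
    """Build the binomial random-regression design for a model variant.

    The response is (n_fledged successes, 4 - n_fledged failures) per
    nest.  The relative lay date is centred on the empirical annual mean of
    the rows supplied; covariate variants add year, SST or log population
    size columns per the model roster.
    """
    breeding = _validate_breeding(breeding)
    df = breeding.copy()

    year_mean = df.groupby("year")["lay_date"].transform("mean")
    rel = (df["lay_date"] - year_mean).to_numpy(dtype=float)
    years = np.sort(df["year"].unique())
    annual = df.groupby("year")["lay_date"].mean()
    grand = annual.mean()
    xbar_c = (year_mean - grand).to_numpy(dtype=float)
    year_c_by_year = pd.Series(years - years.mean(), index=years)
    year_c = year_c_by_year.loc[df["year"]].to_numpy(dtype=float)

    cols = {"intercept": np.ones(len(df)),
            "mean_laydate": xbar_c,
            "rel_laydate": rel}
    if spec.include_quadratic:
        cols["rel_laydate_sq"] = rel**2

    needs_context = spec.variant in ("core_popsize", "sst_current",
                                     "sst_previous")
    ctx = None
    if needs_context:
        if context is None:
            raise ValueError(f"variant {spec.variant!r} requires a context "
                             "table (env covariates)")
        ctx = context.set_index("year")
        absent = [int(y) for y in years if y not in ctx.index]
        if absent:
            raise ValueError(f"context table lacks years: {absent}")

    if spec.variant == "core_popsize":
        logpop = np.log(ctx.loc[df["year"], "population_size"]
                        .to_numpy(dtype=float))
        cols["log_popsize"] = logpop - np.log(
            ctx.loc[years, "population_size"].to_numpy(dtype=float)).mean()
    elif spec.variant == "year":
        cols["year_c"] = year_c
        cols["rel_x_year"] = rel * year_c
    elif spec.variant in ("sst_current", "sst_previous"):
        col = "sst" if spec.variant == "sst_current" else "sst_prev"
        sst_by_year = ctx.loc[years, col].astype(float)
        sst_c = (ctx.loc[df["year"], col].to_numpy(dtype=float)
                 - sst_by_year.mean())
        cols["year_c"] = year_c
        cols[f"{col}_c"] = sst_c
        cols[f"rel_x_{col}"] = rel * sst_c

    X = np.column_stack(list(cols.values()))
    year_index = pd.Series(np.arange(years.size), index=years)
    return ModelDesign(
        X=X, colnames=list(cols),
        U=np.column_stack([np.ones(len(df)), rel]),
        re_names=["year_intercept", "year_rel_slope"],
        year_idx=year_index.loc[df["year"]].to_numpy(),
        years=years,
        family=np.full(len(df), "binomial"),
        y=df["n_fledged"].to_numpy(dtype=float),
        trials=np.full(len(df), float(MAX_BROOD)),
        meta={"grand_mean_laydate": float(grand),
              "variant": spec.variant,
              "year_mean_laydate": annual.to_dict()},
    )


def build_diet_design(diet: pd.DataFrame, variant: str = "sandeel_core",
                      ) -> ModelDesign:
    """Gaussian random-regression design for the offset-logit diet response.

    Relative sample date is centred on the annual mean collection date;
    the between-year covariate is the (grand-centred) annual mean
    collection date (core) or calendar year plus its interaction with
    relative date (year variant).
    """
    if variant not in DIET_VARIANTS:
        raise ValueError(f"unknown diet variant {variant!r}")
    required = {"year", "sample_date", "prop_oneplus"}
    missing = required - set(diet.columns)
    if missing:
        raise ValueError(f"diet table lacks columns: {sorted(missing)}")
    from .transforms import logit_offset

    df = diet.copy()
    year_mean = df.groupby("year")["sample_date"].transform("mean")
    rel = (df["sample_date"] - year_mean).to_numpy(dtype=float)
    years = np.sort(df["year"].unique())
    annual = df.groupby("year")["sample_date"].mean()

    cols = {"intercept": np.ones(len(df))}
    if variant == "sandeel_core":
        cols["mean_sample_date"] = (year_mean - annual.mean()).to_numpy(float)
        cols["rel_sample_date"] = rel
    else:
        year_c = pd.Series(years - years.mean(), index=years)
        yc = year_c.loc[df["year"]].to_numpy(dtype=float)
        cols["year_c"] = yc
        cols["rel_sample_date"] = rel
        cols["rel_x_year"] = rel * yc

    year_index = pd.Series(np.arange(years.size), index=years)
    return ModelDesign(
        X=np.column_stack(list(cols.values())), colnames=list(cols),
        U=np.column_stack([np.ones(len(df)), rel]),
        re_names=["year_intercept", "year_rel_slope"],
        year_idx=year_index.loc[df["year"]].to_numpy(),
        years=years,
        family=np.full(len(df), "gaussian"),
        y=logit_offset(df["prop_oneplus"].to_numpy(dtype=float)),
        trials=np.full(len(df), np.nan),
        meta={"variant": variant},
    )


def build_bivariate_design(breeding: pd.DataFrame, diet: pd.DataFrame,
                           context: Optional[pd.DataFrame] = None,
                           ) -> Tuple[ModelDesign, Dict]:
    """Joint design for breeding success (binomial) and diet (Gaussian).

    Relative timing for BOTH traits is centred on the annual mean lay date
    of the breeding table; diet-only years fall back to the context table's
    mean lay date if provided, else their own mean sample date (counted in
    the returned info dict).  Year-level random effects are ordered
    (B_Sh, B_Sa, W_Sh, W_Sa).
    """
    breeding = _validate_breeding(breeding)
    from .transforms import logit_offset

    b_years = np.sort(breeding["year"].unique())
    d_years = np.sort(diet["year"].unique())
    overlap = np.intersect1d(b_years, d_years)
    if overlap.size < 3:
        raise ValueError(
            f"need >= 3 overlapping years, got {overlap.size}")
    years = np.unique(np.concatenate([b_years, d_years]))
    year_index = pd.Series(np.arange(years.size), index=years)

    mean_lay = breeding.groupby("year")["lay_date"].mean()
    fallback_years = []
    centre = {}
    for y in years:
        if y in mean_lay.index:
            centre[y] = mean_lay.loc[y]
        elif (context is not None
              and y in context.set_index("year").index
              and "mean_lay_date" in context.columns):
            centre[y] = float(
                context.set_index("year").loc[y, "mean_lay_date"])
            fallback_years.append(int(y))
        else:
            centre[y] = diet.loc[diet["year"] == y, "sample_date"].mean()
            fallback_years.append(int(y))
    centre = pd.Series(centre)
    grand = mean_lay.mean()

    # breeding-trait rows
    rel_b = (breeding["lay_date"]
             - centre.loc[breeding["year"]].to_numpy()).to_numpy(float)
    xbar_b = centre.loc[breeding["year"]].to_numpy(float) - grand
    nb = len(breeding)
    # diet-trait rows
    rel_d = (diet["sample_date"]
             - centre.loc[diet["year"]].to_numpy()).to_numpy(float)
    xbar_d = centre.loc[diet["year"]].to_numpy(float) - grand
    nd = len(diet)

    colnames = ["sh_intercept", "sh_mean_laydate", "sh_rel_laydate",
                "sh_rel_laydate_sq", "sa_intercept", "sa_mean_laydate",
                "sa_rel_laydate"]
    X = np.zeros((nb + nd, len(colnames)))
    X[:nb, 0] = 1.0
    X[:nb, 1] = xbar_b
    X[:nb, 2] = rel_b
    X[:nb, 3] = rel_b**2
    X[nb:, 4] = 1.0
    X[nb:, 5] = xbar_d
    X[nb:, 6] = rel_d

    re_names = ["B_Sh", "B_Sa", "W_Sh", "W_Sa"]
    U = np.zeros((nb + nd, 4))
    U[:nb, 0] = 1.0
    U[:nb, 2] = rel_b
    U[nb:, 1] = 1.0
    U[nb:, 3] = rel_d

    design = ModelDesign(
        X=X, colnames=colnames, U=U, re_names=re_names,
        year_idx=np.concatenate([
            year_index.loc[breeding["year"]].to_numpy(),
            year_index.loc[diet["year"]].to_numpy()]),
        years=years,
        family=np.concatenate([np.full(nb, "binomial"),
                               np.full(nd, "gaussian")]),
        y=np.concatenate([breeding["n_fledged"].to_numpy(dtype=float),
                          logit_offset(diet["prop_oneplus"]
                                       .to_numpy(dtype=float))]),
        trials=np.concatenate([np.full(nb, float(MAX_BROOD)),
                               np.full(nd, np.nan)]),
        meta={"variant": "bivariate", "grand_mean_laydate": float(grand)},
    )
    info = {"fallback_centre_years": fallback_years,
            "n_overlap_years": int(overlap.size)}
    return design, info
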