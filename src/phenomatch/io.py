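"""CSV readers and validators for the three input tables.

Schemas (all dates as integer ordinal days, January 1st = 0):

* ``breeding.csv`` — year, nest_id, lay_date, n_fledged, optional attempt
* ``env.csv``      — year, sst, sst_prev, population_size
* ``diet.csv``     — year, sample_date, prop_oneplus
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .design import MAX_BROOD

logger = logging.getLogger(__name__)


def _require(df: pd.DataFrame, cols, what: str) -> None:
    missing = set(cols) - set(df.columns)
    if missing:
        raise ValueError(f"{what} lacks required columns: {sorted(missing)}")


def read_breeding_csv(path) -> pd.DataFrame:
    """Read and validate nest-level breeding records.

    Rows with attempt > 1 (replacement clutches) are dropped with a logged
    count; duplicate (year, nest_id) pairs and fledged counts outside
    0..4 raise with the offending row numbers (1-based, excluding header).
    """
    df = pd.read_csv(path)
    _require(df, ["year", "nest_id", "lay_date", "n_fledged"],
             "breeding table")
    if "attempt" in df.columns:
        drop = df["attempt"] > 1
        if drop.any():
            logger.info("dropped %d replacement-clutch rows (attempt > 1)",
                        int(drop.sum()))
        df = df.loc[~drop].drop(columns="attempt").reset_index(drop=True)

    fledged = pd.to_numeric(df["n_fledged"], errors="coerce")
    bad = df.index[fledged.isna() | (fledged != fledged.round())]
    if len(bad):
        raise ValueError(
            f"non-integer n_fledged at rows {(bad + 1).tolist()}")
    out_of_range = df.index[(fledged < 0) | (fledged > MAX_BROOD)]
    if len(out_of_range):
        raise ValueError(f"n_fledged outside 0..{MAX_BROOD} at rows "
                         f"{(out_of_range + 1).tolist()}")
    dup = df.duplicated(subset=["year", "nest_id"])
    if dup.any():
        raise ValueError(f"duplicate (year, nest_id) at rows "
                         f"{(df.index[dup] + 1).tolist()}")
    df["year"] = df["year"].astype(int)
    df["lay_date"] = df["lay_date"].astype(int)
    df["n_fledged"] = fledged.astype(int)
    return df


def read_env_csv(path) -> pd.DataFrame:
    """Read annual environmental covariates (SST, lagged SST, pairs)."""
    df = pd.read_csv(path)
    _require(df, ["year", "sst"], "environment table")
    if df["year"].duplicated().any():
        raise ValueError("environment table has duplicated years")
    if "sst_prev" not in df.columns:
        df = df.sort_values("year").reset_index(drop=True)
        df["sst_prev"] = df["sst"].shift(1)
        logger.info("sst_prev derived by lagging sst (first year missing)")
    df["year"] = df["year"].astype(int)
    return df


def read_diet_csv(path) -> pd.DataFrame:
    """Read regurgitate diet samples; proportions must lie in [0, 1]."""
    df = pd.read_csv(path)
    _require(df, ["year", "sample_date", "prop_oneplus"], "diet table")
    p = df["prop_oneplus"].to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(p) | (p < 0) | (p > 1))
    if bad.size:
        raise ValueError(f"prop_oneplus outside [0, 1] at rows "
                         f"{(bad + 1).tolist()}")
    df["year"] = df["year"].astype(int)
    df["sample_date"] = df["sample_date"].astype(int)
    return df


def make_year_context(breeding: pd.DataFrame,
                      env: pd.DataFrame | None = None,
                      diet: pd.DataFrame | None = None) -> pd.DataFrame:
    """Assemble the one-row-per-year covariate table used by the models."""
    ctx = breeding.groupby("year")["lay_date"].mean() \
        .rename("mean_lay_date").reset_index()
    if env is not None:
        ctx = ctx.merge(env, on="year", how="left")
    if diet is not None:
        mean_sample = diet.groupby("year")["sample_date"].mean() \
            .rename("mean_sample_date").reset_index()
        ctx = ctx.merge(mean_sample, on="year", how="left")
    return ctx
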