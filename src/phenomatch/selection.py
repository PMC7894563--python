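"""Posterior summaries and derived selection statistics.

All derived quantities are computed draw-by-draw and then summarised, so
nonlinear functions of coefficients (the quadratic vertex -b/2a, the
optimum-advance rate B) carry full posterior uncertainty rather than being
ratios of posterior means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd

from .mcmc import PosteriorSamples
from .trends import TrendFit

CI_LEVEL = 0.95


def _ci(draws: np.ndarray, level: float = CI_LEVEL) -> Tuple[float, float]:
    lo = (1.0 - level) / 2.0
    q = np.quantile(draws, [lo, 1.0 - lo])
    return float(q[0]), float(q[1])


def summarize(posterior: PosteriorSamples) -> pd.DataFrame:
    """Coefficient table: posterior mean, 95% credible interval, and a
    significance flag (CI excludes zero) for each fixed effect and
    year-level (co)variance component."""
    if posterior.n_draws < 100:
        raise ValueError(
            f"need >= 100 retained draws, have {posterior.n_draws}")
    rows = []
    for j, name in enumerate(posterior.fixed_names):
        d = posterior.fixed[:, j]
        lo, hi = _ci(d)
        rows.append((name, "fixed", float(d.mean()), lo, hi,
                     bool(lo > 0 or hi < 0)))
    q = len(posterior.re_names)
    for i in range(q):
        for j in range(i, q):
            d = posterior.cov[:, i, j]
            lo, hi = _ci(d)
            label = (f"var({posterior.re_names[i]})" if i == j else
                     f"cov({posterior.re_names[i]},{posterior.re_names[j]})")
            rows.append((label, "random", float(d.mean()), lo, hi,
                         bool(lo > 0 or hi < 0)))
    if posterior.resid_var is not None:
        d = posterior.resid_var
        lo, hi = _ci(d)
        rows.append(("resid_var", "residual", float(d.mean()), lo, hi, True))
    return pd.DataFrame(rows, columns=["parameter", "kind", "mean",
                                       "ci_low", "ci_high", "significant"])


@dataclass
class VertexEstimate:
    """Posterior of the fitness-peak date relative to the annual mean."""

    mean: float
    ci_low: float
    ci_high: float
    draws: np.ndarray
    n_excluded: int


def vertex(posterior: PosteriorSamples,
           linear: str = "rel_laydate",
           quadratic: str = "rel_laydate_sq") -> VertexEstimate:
    """Quadratic-peak date -b/2a per draw (days relative to annual mean).

    Negative values mean the fitness peak lies before the annual mean lay
    date.  Draws with an exactly zero quadratic coefficient are excluded
    (with a warning if they exceed 5%).
    """
    b = posterior.get(linear)
    a = posterior.get(quadratic)
    ok = a != 0.0
    n_excl = int((~ok).sum())
    if n_excl > 0.05 * a.size:
        warnings.warn(f"{n_excl} of {a.size} draws had a zero quadratic "
                      "coefficient and were excluded from the vertex",
                      UserWarning, stacklevel=2)
    if ok.sum() == 0:
        raise ValueError("all quadratic draws are exactly zero")
    v = -b[ok] / (2.0 * a[ok])
    lo, hi = _ci(v)
    return VertexEstimate(mean=float(v.mean()), ci_low=lo, ci_high=hi,
                          draws=v, n_excluded=n_excl)


@dataclass
class VarianceEstimate:
    mean: float
    ci_low: float
    ci_high: float
    draws: np.ndarray


def slope_variance(posterior: PosteriorSamples,
                   component: str = "year_rel_slope") -> VarianceEstimate:
    """Among-year variance of the within-year selection slope."""
    d = posterior.cov_entry(component, component)
    lo, hi = _ci(d)
    return VarianceEstimate(mean=float(d.mean()), ci_low=lo, ci_high=hi,
                            draws=d)


@dataclass
class SensitivityEstimate:
    """Rate of change of the optimum lay date per unit of environment (B).

    ``mean`` combines the trend in mean timing with the posterior of the
    relative-optimum shift; the CI propagates both the posterior draws and
    the timing-trend slope's sampling SE.
    """

    mean: float
    ci_low: float
    ci_high: float
    timing_trend_component: float
    relative_optimum_component: float
    covariate: str
    draws: np.ndarray = field(repr=False, default=None)


_INTERACTION_COLS = {"year": "rel_x_year",
                     "sst": "rel_x_sst",
                     "sst_prev": "rel_x_sst_prev"}


def optimum_sensitivity(posterior: PosteriorSamples,
                        timing_trend: TrendFit,
                        covariate: str = "year",
                        seed: int = 0) -> SensitivityEstimate:
    """Advance rate of the absolute optimum lay date per unit covariate.

    The absolute optimum in environment state E is the annual mean timing
    plus the within-year vertex, O(E) = xbar(E) - (b + b_int * E)/(2a), so
    its derivative is B = dxbar/dE - b_int/(2a): the mean-timing trend
    slope plus the posterior shift of the relative optimum.  The CI adds
    the trend slope's sampling SE to the posterior draws in quadrature on
    the draw scale.
    """
    col = _INTERACTION_COLS.get(covariate)
    if col is None:
        raise ValueError(f"covariate must be one of {list(_INTERACTION_COLS)}")
    if col not in posterior.fixed_names:
        needed = {"year": "year", "sst": "sst_current",
                  "sst_prev": "sst_previous"}[covariate]
        raise ValueError(
            f"posterior lacks the {col!r} interaction; fit the "
            f"{needed!r} model variant")
    b_int = posterior.get(col)
    a = posterior.get("rel_laydate_sq")
    ok = a != 0.0
    rel_opt = -b_int[ok] / (2.0 * a[ok])
    rng = np.random.default_rng(seed)
    jitter = rng.normal(0.0, timing_trend.slope_se, size=ok.sum())
    draws = timing_trend.slope + jitter + rel_opt
    lo, hi = _ci(draws)
    mean = float(timing_trend.slope + rel_opt.mean())
    return SensitivityEstimate(
        mean=mean, ci_low=lo, ci_high=hi,
        timing_trend_component=float(timing_trend.slope),
        relative_optimum_component=float(rel_opt.mean()),
        covariate=covariate, draws=draws)


def covariance_summary(posterior: PosteriorSamples) -> pd.DataFrame:
    """Year-level covariance matrix summary for a (multi-trait) fit.

    One row per upper-triangle entry: posterior mean, 95% CI, the CI-
    excludes-zero flag, the posterior probability of a positive value, and
    (for off-diagonal entries) the posterior mean correlation.
    """
    if posterior.n_draws < 100:
        raise ValueError(
            f"need >= 100 retained draws, have {posterior.n_draws}")
    names = posterior.re_names
    q = len(names)
    rows = []
    for i in range(q):
        for j in range(i, q):
            d = posterior.cov[:, i, j]
            lo, hi = _ci(d)
            if i == j:
                corr = 1.0
            else:
                denom = np.sqrt(posterior.cov[:, i, i]
                                * posterior.cov[:, j, j])
                corr = float(np.mean(d / denom))
            rows.append({
                "entry": (f"var({names[i]})" if i == j
                          else f"cov({names[i]},{names[j]})"),
                "trait_a": names[i], "trait_b": names[j],
                "mean": float(d.mean()), "ci_low": lo, "ci_high": hi,
                "significant": bool(lo > 0 or hi < 0),
                "p_positive": float((d > 0).mean()),
                "correlation": corr,
            })
    return pd.DataFrame(rows)
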