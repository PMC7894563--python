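"""Temporal-trend and correlation estimators.

Annual series in this system are short (about 30 points) and serially
correlated, so linear trends are estimated by generalised least squares
with an AR(1) error structure, with the autocorrelation phi profiled out by
maximum likelihood.  Because monitoring has gap years, the time axis is the
calendar year itself and the error correlation between two observations is
phi**|t1 - t2| — a missing year widens the lag rather than being ignored.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve


@dataclass
class TrendFit:
    """A fitted linear trend: slope, SE, two-sided p-value and AR(1) phi."""

    slope: float
    slope_se: float
    intercept: float
    p_value: float
    phi: float
    n: int


@dataclass
class CorrelationResult:
    """Pearson correlation with a Fisher-z 95% confidence interval."""

    r: float
    ci_low: float
    ci_high: float
    n: int
    p_value: float


def _validate_xy(x, y, min_n):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be one-dimensional and equally long")
    bad = np.flatnonzero(~(np.isfinite(x) & np.isfinite(y)))
    if bad.size:
        raise ValueError(f"non-finite values at rows {bad.tolist()}")
    if x.size < min_n:
        raise ValueError(f"need at least {min_n} pairs, got {x.size}")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    return x, y


def _ar1_profile_negloglik(phi: float, x: np.ndarray, y: np.ndarray) -> float:
    """Concentrated (profile) negative log-likelihood of phi.

    For fixed phi, the GLS estimates of intercept/slope and the error scale
    have closed forms; this returns the resulting profile -2-free loglik.
    """
    n = x.size
    lags = np.abs(x[:, None] - x[None, :])
    corr = phi ** lags / (1.0 - phi**2)
    c, low = cho_factor(corr, lower=True)
    X = np.column_stack([np.ones(n), x])
    ciX = cho_solve((c, low), X)
    ciy = cho_solve((c, low), y)
    beta = np.linalg.solve(X.T @ ciX, X.T @ ciy)
    r = y - X @ beta
    ssr = float(r @ cho_solve((c, low), r))
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    # residual variance profiled out; guard the exactly-linear case
    ssr = max(ssr, 1e-300)
    return 0.5 * (n * np.log(ssr / n) + logdet)


def fit_gls_ar1(x, y, phi: float | None = None) -> TrendFit:
    """Linear trend of ``y`` on ``x`` with AR(1)-correlated errors.

    Parameters
    ----------
    x, y : array-like
        Yearly predictor (the time axis, gaps allowed) and response.
    phi : float, optional
        Fix the AR(1) coefficient instead of estimating it; ``phi=0``
        reproduces ordinary least squares.

    Returns
    -------
    TrendFit
        Slope, SE and two-sided p-value (t distribution, n - 2 df) under
        the estimated error correlation phi**|lag|.
    """
    x, y = _validate_xy(x, y, min_n=4)
    if phi is None:
        res = optimize.minimize_scalar(
            _ar1_profile_negloglik, bounds=(-0.98, 0.98), args=(x, y),
            method="bounded", options={"xatol": 1e-6})
        phi_hat = float(res.x)
        # prefer the OLS boundary when the likelihood is flat near zero
        if (_ar1_profile_negloglik(0.0, x, y)
                <= _ar1_profile_negloglik(phi_hat, x, y) + 1e-10):
            phi_hat = 0.0
    else:
        if abs(phi) >= 1.0:
            raise ValueError("|phi| must be < 1")
        phi_hat = float(phi)

    n = x.size
    X = sm.add_constant(x)
    lags = np.abs(x[:, None] - x[None, :])
    sigma = phi_hat ** lags / (1.0 - phi_hat**2)
    fit = sm.GLS(y, X, sigma=sigma).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    if se > 0:
        p = 2.0 * stats.t.sf(abs(slope / se), df=n - 2)
    else:  # exactly collinear response
        p = 0.0 if slope != 0 else 1.0
    return TrendFit(slope=slope, slope_se=se, intercept=float(fit.params[0]),
                    p_value=float(p), phi=phi_hat, n=n)


def fit_ols(x, y) -> TrendFit:
    """Ordinary least-squares linear trend (AR(1) phi fixed at zero)."""
    x, y = _validate_xy(x, y, min_n=3)
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    slope = float(fit.params[1])
    se = float(fit.bse[1])
    if se > 0:
        p = 2.0 * stats.t.sf(abs(slope / se), df=x.size - 2)
    else:
        p = 0.0 if slope != 0 else 1.0
    return TrendFit(slope=slope, slope_se=se, intercept=float(fit.params[0]),
                    p_value=float(p), phi=0.0, n=x.size)


def pearson_ci(x, y) -> CorrelationResult:
    """Pearson correlation with a 95% CI from the Fisher z-transform."""
    x, y = _validate_xy(x, y, min_n=4)
    if np.ptp(y) == 0:
        raise ValueError("response is constant")
    r, p = stats.pearsonr(x, y)
    n = x.size
    if abs(r) >= 1.0:
        lo = hi = float(np.sign(r))
    else:
        z = np.arctanh(r)
        half = 1.96 / np.sqrt(n - 3)
        lo, hi = np.tanh(z - half), np.tanh(z + half)
    return CorrelationResult(r=float(r), ci_low=float(lo), ci_high=float(hi),
                             n=n, p_value=float(p))
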