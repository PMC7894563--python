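"""Generative parameter set for the synthetic colony.

The defaults describe a 30-year seabird study system: late-winter sea
surface temperature (SST) warming slowly with AR(1) interannual noise, an
advancing population mean lay date, nest-level fledging success (out of a
maximum brood of four) that declines both with the annual mean lay date
(between-year effect) and with a nest's lay date relative to that mean
(within-year directional plus stabilising selection), and colony-level diet
samples whose proportion of older (1+ group) sandeels declines through each
season.  Year-level random intercepts and relative-timing slopes of the two
traits (breeding success and diet) are drawn jointly from a 4x4 covariance
matrix so that trophic-mismatch couplings can be switched on.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

#: Row/column order of the year-level 4x4 covariance matrix: breeding-success
#: intercept (B_Sh), diet intercept (B_Sa), breeding-success relative-timing
#: slope (W_Sh), diet relative-timing slope (W_Sa).
CROSS_COV_ORDER = ("B_Sh", "B_Sa", "W_Sh", "W_Sa")


@dataclass
class SimulationParams:
    """Full generative parameter set; defaults emulate the study system."""

    # -- study frame -------------------------------------------------------
    n_years: int = 30
    start_year: int = 1987
    nests_per_year: Tuple[int, int] = (35, 266)
    gap_years: Tuple[int, ...] = (1993, 2003)

    # -- SST series (deg C) ------------------------------------------------
    sst_mean: float = 5.94
    sst_trend: float = 0.02          # deg C / year
    sst_ar_phi: float = 0.27
    sst_sd: float = 0.35             # innovation SD of the AR(1) noise

    # -- lay-date phenology (ordinal days) ---------------------------------
    laydate_intercept: float = 127.0
    laydate_trend: float = -0.94     # days / year
    laydate_sst_slope: float = -6.30  # days / deg C
    laydate_year_sd: float = 5.0     # annual-mean noise, days
    laydate_within_sd: float = 12.0  # nest spread within a year, days

    # -- breeding success, latent logit scale ------------------------------
    mu: float = -0.9
    beta_B: float = -0.035           # per day of annual mean lay date
    beta_W: float = -0.026           # per day of relative lay date
    gamma: float = -0.0007           # per day^2 (quadratic)
    beta_W_year: float = 0.0         # relative-date x year interaction
    beta_W_sst: float = 0.0          # relative-date x SST interaction
    sigma2_int: float = 0.3          # year intercept variance (logit^2)
    sigma2_slope: float = 1e-4       # year slope variance ((logit/day)^2)
    rho_int_slope: float = 0.0
    resid_sd: float = 1.0            # latent residual SD, fixed at 1

    # -- diet seasonality, offset-logit scale ------------------------------
    diet_mu: float = 0.5
    diet_within_slope: float = -0.095   # logit / day
    diet_sigma2_int: float = 6.46
    diet_sigma2_slope: float = 0.015
    diet_resid_sd: float = 0.8
    diet_date_offset: float = 40.0   # mean sample date minus mean lay date
    diet_date_sd: float = 10.0
    samples_per_year: Tuple[int, int] = (4, 69)

    # -- year-level cross-trait covariance ---------------------------------
    cross_cov: Optional[np.ndarray] = None  # 4x4 over CROSS_COV_ORDER
    cov_BSh_BSa: float = -0.363
    cov_WSh_WSa: float = 0.0003

    def __post_init__(self) -> None:
        if self.n_years < 3:
            raise ValueError("n_years must be at least 3")
        if self.nests_per_year[0] < 1:
            raise ValueError("nests_per_year minimum must be >= 1")
        if self.samples_per_year[0] < 1:
            raise ValueError("samples_per_year minimum must be >= 1")
        for name in ("sigma2_int", "sigma2_slope", "diet_sigma2_int",
                     "diet_sigma2_slope"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if abs(self.rho_int_slope) > 1:
            raise ValueError("|rho_int_slope| must be <= 1")
        if self.cross_cov is not None:
            self.cross_cov = np.asarray(self.cross_cov, dtype=float)
            _check_psd(self.cross_cov, "cross_cov")

    # ------------------------------------------------------------------
    def year_range(self) -> np.ndarray:
        """Simulated calendar years before gap years are dropped."""
        return np.arange(self.start_year, self.start_year + self.n_years)

    def kept_years(self) -> np.ndarray:
        """Calendar years retained after dropping gap years."""
        years = self.year_range()
        return years[~np.isin(years, np.asarray(self.gap_years, dtype=int))]

    def effective_cross_cov(self) -> np.ndarray:
        """The 4x4 year-level covariance actually used by the generator.

        When ``cross_cov`` is not supplied it is assembled from the marginal
        variance fields, ``rho_int_slope`` and the two named cross-trait
        covariances, with the remaining cross entries zero.
        """
        if self.cross_cov is not None:
            return self.cross_cov
        s = np.zeros((4, 4))
        s[0, 0] = self.sigma2_int
        s[1, 1] = self.diet_sigma2_int
        s[2, 2] = self.sigma2_slope
        s[3, 3] = self.diet_sigma2_slope
        s[0, 2] = s[2, 0] = (self.rho_int_slope
                             * np.sqrt(self.sigma2_int * self.sigma2_slope))
        s[0, 1] = s[1, 0] = self.cov_BSh_BSa
        s[2, 3] = s[3, 2] = self.cov_WSh_WSa
        _check_psd(s, "cross_cov")
        return s

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        if d["cross_cov"] is not None:
            d["cross_cov"] = np.asarray(d["cross_cov"]).tolist()
        for key in ("nests_per_year", "samples_per_year", "gap_years"):
            d[key] = list(d[key])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationParams":
        d = dict(d)
        if d.get("cross_cov") is not None:
            d["cross_cov"] = np.asarray(d["cross_cov"], dtype=float)
        for key in ("nests_per_year", "samples_per_year", "gap_years"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


def _check_psd(m: np.ndarray, name: str, tol: float = 1e-10) -> None:
    m = np.asarray(m, dtype=float)
    if m.shape != (4, 4) or not np.allclose(m, m.T, atol=1e-12):
        raise ValueError(f"{name} must be a symmetric 4x4 matrix")
    w = np.linalg.eigvalsh(m)
    if w.min() < -tol * max(1.0, w.max()):
        raise ValueError(f"{name} is not positive semi-definite "
                         f"(min eigenvalue {w.min():.3g})")


@dataclass
class GroundTruth:
    """Record of the generative state behind one synthetic dataset."""

    params: SimulationParams
    seed: int
    #: per kept year, the realised 4-vector (B_Sh, B_Sa, W_Sh, W_Sa)
    year_effects: np.ndarray = field(default_factory=lambda: np.empty((0, 4)))
    years: Sequence[int] = ()

    def to_json(self, path) -> None:
        payload = {
            "params": self.params.to_dict(),
            "seed": int(self.seed),
            "years": [int(y) for y in self.years],
            "year_effect_order": list(CROSS_COV_ORDER),
            "year_effects": np.asarray(self.year_effects).tolist(),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(
            params=SimulationParams.from_dict(payload["params"]),
            seed=payload["seed"],
            year_effects=np.asarray(payload["year_effects"], dtype=float),
            years=payload["years"],
        )
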