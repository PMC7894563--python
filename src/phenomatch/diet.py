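"""Seasonal diet-shift models.

The proportion of older (1+ group) sandeels among all sandeels in each
regurgitate is mapped to the real line by the offset logit and modelled as
Gaussian with year-level random intercepts and relative-collection-date
slopes.  The core variant tests whether years sampled later carry fewer
1+ group sandeels (between-year) and whether the proportion declines
through each season (within-year); the year variant asks whether either
trend changed over the study.
"""

from __future__ import annotations

import logging
from typing import Optional

import pandas as pd

from .design import build_diet_design
from .mcmc import MCMCSettings, PosteriorSamples, PriorSpec, fit_model
from .transforms import inv_logit_offset, logit_offset  # re-export

__all__ = ["fit_diet_model", "logit_offset", "inv_logit_offset"]

logger = logging.getLogger(__name__)


def fit_diet_model(diet: pd.DataFrame, variant: str = "sandeel_core",
                   mcmc: Optional[MCMCSettings] = None,
                   prior: Optional[PriorSpec] = None) -> PosteriorSamples:
    """Fit a Gaussian random-regression model to offset-logit proportions.

    Years with a single sample cannot inform the within-year slope; they
    are retained (they still inform intercepts) and logged.
    """
    counts = diet.groupby("year").size()
    singletons = counts.index[counts < 2].tolist()
    if singletons:
        logger.info("years with a single diet sample (inform intercepts "
                    "only): %s", singletons)
    design = build_diet_design(diet, variant=variant)
    if design.n_years < 3:
        raise ValueError("need at least 3 years of diet samples")
    if mcmc is None:
        mcmc = MCMCSettings()
    return fit_model(design, mcmc, prior)
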