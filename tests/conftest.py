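import numpy as np
import pytest

from phenomatch import (MCMCSettings, ModelSpec, SimulationParams,
                        build_design, fit_model, simulate_dataset)
from phenomatch.mcmc import PosteriorSamples


@pytest.fixture(scope="session")
def small_params() -> SimulationParams:
    """A reduced study frame (10 years, 40 nests) for fast model fits."""
    return SimulationParams(n_years=10, nests_per_year=(40, 40),
                            samples_per_year=(8, 20), gap_years=())


@pytest.fixture(scope="session")
def small_dataset(small_params):
    return simulate_dataset(small_params, seed=1234)


@pytest.fixture(scope="session")
def core_posterior(small_dataset):
    """One moderately long core-model fit shared across tests."""
    design = build_design(small_dataset["breeding"], None, ModelSpec("core"))
    return fit_model(design, MCMCSettings(n_iterations=6000, burn_in=1000,
                                          thin=5, seed=77))


def make_posterior(fixed: dict, cov: np.ndarray | None = None,
                   re_names=("year_intercept", "year_rel_slope"),
                   resid_var=None) -> PosteriorSamples:
    """Fabricate a PosteriorSamples object from explicit draw arrays."""
    names = list(fixed)
    arr = np.column_stack([np.asarray(fixed[k], dtype=float) for k in names])
    n = arr.shape[0]
    q = len(re_names)
    if cov is None:
        cov = np.broadcast_to(np.eye(q), (n, q, q)).copy()
    settings = MCMCSettings(n_iterations=n * 10 + 10, burn_in=10, thin=10,
                            seed=0)
    return PosteriorSamples(
        fixed=arr, fixed_names=names, cov=np.asarray(cov, dtype=float),
        re_names=list(re_names), u=np.zeros((n, 1, q)),
        years=np.arange(1), resid_var=resid_var, settings=settings)
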