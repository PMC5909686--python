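import numpy as np
import pandas as pd
import pytest

from reeftransfer import SystemConfig, generate_system


PREDICTORS = ["coast", "barrier", "slope", "depth", "crbnt", "gravel", "sand", "mud",
              "NO3_av", "PO4_av", "SI_av", "O2_av", "Sal_av", "Chla_av", "SST_av",
              "K490_av"]


def full_ranges(shift: float = 0.0) -> dict:
    return {p: (0.0 + shift, 10.0 + shift) for p in PREDICTORS}


@pytest.fixture(scope="session")
def small_system():
    """A compact reference-style system: 12 reefs x 3 sites, 2 years."""
    cfg = SystemConfig(
        "REF", n_reefs=12, sites_per_reef=3, transects_per_site=5,
        years=(2007, 2013),
        beta={"Intercept": np.log(200.0), "NO3_av": 0.5, "depth": -0.3, "depth2": -0.2},
        sigma_alpha=0.4, theta=4.0, covariate_ranges=full_ranges(),
        seed=101, grid_step_deg=0.1,
    )
    survey, grid, truth = generate_system(cfg)
    return cfg, survey, grid, truth


def simulate_glmm_counts(seed, n_reefs=50, sites=20, beta0=1.0, beta1=0.5,
                         sigma=0.5, theta=5.0):
    """Direct NB2 + random-intercept draw used as the recovery oracle."""
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n_reefs * sites)
    reefs = np.repeat(np.arange(n_reefs), sites)
    alpha = rng.normal(0.0, sigma, n_reefs)
    mu = np.exp(beta0 + beta1 * x + alpha[reefs])
    y = rng.negative_binomial(theta, theta / (theta + mu))
    return pd.DataFrame({"x": x}), y, reefs
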