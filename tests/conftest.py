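import numpy as np
import pandas as pd
import pytest

import nof1bayes as nb
from nof1bayes.hierarchical import McmcSettings, ModelSpec
from nof1bayes.simulate import SERIES_COLUMNS


def make_single_patient(
    effect: float,
    resid_sd: float,
    n_pairs: int = 2,
    obs_per_period: int = 10,
    seed: int = 0,
    mu: float = 4.2,
) -> pd.DataFrame:
    """One patient's series with a known individual effect."""
    params = nb.CohortParams(
        mu=mu, beta0=effect, sigma_intercept=0.0, sigma_slope=0.0, sigma_resid=resid_sd
    )
    orders = nb.randomize_orders(n_pairs, seed)
    return nb.simulate_trial(
        params, (0.0, 0.0, resid_sd), n_pairs, obs_per_period, orders, seed=seed
    )


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """A 30-patient cohort under the default generator settings."""
    return nb.simulate_cohort(nb.DesignSpec(), nb.CohortParams(), n_pairs=2, seed=2024)


@pytest.fixture(scope="session")
def fast_mcmc() -> McmcSettings:
    return McmcSettings(chains=2, warmup=300, draws=400, seed=11)


@pytest.fixture(scope="session")
def flat_common_model() -> ModelSpec:
    return ModelSpec(
        prior_beta0=nb.PriorSpec.flat(),
        subgroup_fixed_effect=False,
        residual_variance_mode="common",
    )


def conjugate_posterior(
    diff: float, n_active: int, n_placebo: int, resid_sd: float, prior_loc: float, prior_scale: float
) -> tuple[float, float]:
    """Closed-form normal-normal posterior of the effect for one patient.

    With a flat prior on the level, the likelihood for the effect reduces to
    the arm-mean difference with variance resid_sd^2 (1/n_a + 1/n_p).
    """
    lam = 1.0 / (resid_sd**2 * (1.0 / n_active + 1.0 / n_placebo))
    prec = 1.0 / prior_scale**2 + lam
    mean = (prior_loc / prior_scale**2 + lam * diff) / prec
    return mean, prec**-0.5
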