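import numpy as np
import pytest

from pgsa import (
    generate_baseline,
    generate_outcomes,
    mci_endpoint_fixture,
    mci_trajectory_fixture,
)


@pytest.fixture(scope="session")
def endpoint_fit():
    return mci_endpoint_fixture()


@pytest.fixture(scope="session")
def trajectory_fit():
    return mci_trajectory_fixture()


@pytest.fixture(scope="session")
def small_cohort():
    """60 synthetic baselines, fixed seed."""
    return generate_baseline(60, seed=123)


@pytest.fixture(scope="session")
def small_dataset(small_cohort, endpoint_fit, trajectory_fit):
    """Small cohort with simulated endpoint + trajectory outcomes."""
    return generate_outcomes(
        small_cohort,
        endpoint=endpoint_fit,
        trajectory=trajectory_fit,
        seed=321,
        param_uncertainty=False,
    )


def noise_free(fit):
    """Copy of a fit with all stochastic components zeroed (trajectory) or
    near-zeroed where exact zero is disallowed."""
    import dataclasses

    return dataclasses.replace(
        fit,
        cov=np.zeros_like(fit.cov),
        sd_intercept=0.0,
        sd_slope=0.0,
        corr=0.0,
        within_sd=1e-12,
    )
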