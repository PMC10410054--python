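import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import regclock as rc
from regclock.simdata import SimConfig, simulate_cohort

settings.register_profile(
    "default",
    deadline=None,
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (seed 1): raw samples plus ground truth."""
    return simulate_cohort(SimConfig(seed=1))


@pytest.fixture(scope="session")
def filtered_cohort(cohort):
    samples, truth = cohort
    return [rc.filter_low_coverage(s, 5) for s in samples], truth


@pytest.fixture(scope="session")
def region_matrix(filtered_cohort):
    samples, truth = filtered_cohort
    return rc.build_region_matrix(samples, truth.clusters)


@pytest.fixture(scope="session")
def trained_clock(region_matrix):
    """Clock trained on a 90/10 split of the default cohort."""
    cfg = rc.TrainConfig(seed=1)
    train, holdout = rc.split_train_cv(region_matrix, cfg)
    model = rc.train_lasso_clock(train, cfg)
    return model, holdout


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
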