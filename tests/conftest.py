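import numpy as np
import pytest

from petsim import (
    PhantomParams,
    ScoringConfig,
    fit_age_regression,
    make_template_masks,
    simulate_cohort,
)

GRID = (24, 24, 24)


@pytest.fixture(scope="session")
def masks():
    return make_template_masks(GRID)


@pytest.fixture(scope="session")
def phantom_params():
    return PhantomParams(grid_shape=GRID)


@pytest.fixture(scope="session")
def noisefree_params():
    return PhantomParams(grid_shape=GRID, subject_noise_sd=0.0)


@pytest.fixture(scope="session")
def scoring_config():
    return ScoringConfig(pre_normalized=True)


@pytest.fixture(scope="session")
def control_cohort(phantom_params, masks):
    return simulate_cohort(phantom_params, masks, n_nc=20, n_ad=0, seed=11, id_prefix="ctl")


@pytest.fixture(scope="session")
def normal_db(control_cohort, masks, scoring_config):
    return fit_age_regression(control_cohort, masks, scoring_config)


@pytest.fixture(scope="session")
def test_cohort(phantom_params, masks):
    return simulate_cohort(phantom_params, masks, n_nc=6, n_ad=6, seed=23, id_prefix="sub")
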