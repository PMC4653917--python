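import numpy as np
import pytest

from acidnav import (
    PUBLISHED_OPTIMUM,
    SimConfig,
    make_parametric_gradient,
    run_cohort,
)


@pytest.fixture(scope="session")
def optimum_params():
    """The published optimal decision-parameter set."""
    return PUBLISHED_OPTIMUM


@pytest.fixture(scope="session")
def sim_config():
    return SimConfig()


@pytest.fixture(scope="session")
def standard_field():
    """Default assay field: pH 6 far side, 4.0 on the border, 3 in the acid."""
    return make_parametric_gradient(4.0, 0.5, 6.0, 6.0, 3.0)


@pytest.fixture(scope="session")
def shallow_field():
    """Shallow study field spanning both decision centers (pH 6 -> 2)."""
    return make_parametric_gradient(4.0, 1.0, 8.0, 6.0, 2.0)


@pytest.fixture(scope="session")
def steep_field():
    """3x steeper companion of shallow_field."""
    return make_parametric_gradient(4.0, 3.0, 8.0, 6.0, 2.0)


@pytest.fixture(scope="session")
def optimum_cohort(standard_field, optimum_params, sim_config):
    """A 3000-trial cohort at the published optimum on the standard field."""
    return run_cohort(3000, standard_field, optimum_params, sim_config, seed=1)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
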