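import numpy as np
import pytest

from actionprior import PriorSpec, build_level_grid, discretize_gaussian

#: Published per-level frequency table for the 200-trial conditions.
PUBLISHED_COUNTS = (2, 6, 12, 24, 36, 40, 36, 24, 12, 6, 2)


@pytest.fixture
def upward_grid():
    """Experiment-1 upward-bias grid: 0.29-0.59, centre 0.44."""
    return build_level_grid(-0.06, 0.03, 11)


@pytest.fixture
def downward_grid():
    """Experiment-1 downward-bias grid: 0.41-0.71, centre 0.56."""
    return build_level_grid(+0.06, 0.03, 11)


@pytest.fixture
def upward_prior():
    return PriorSpec(-0.06, 0.06)


@pytest.fixture
def upward_schedule(upward_grid, upward_prior):
    return discretize_gaussian(upward_grid, upward_prior, 200, key="Z")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
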