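import numpy as np
import pytest
from hypothesis import settings

from maekin.models import FirstOrderParams, GlobalParams, LogisticParams
from maekin.simulate import DEFAULT_TIME_GRID

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def time_grid():
    """The 25-point extraction-time grid {1, 5, ..., 120} s."""
    return DEFAULT_TIME_GRID.copy()


@pytest.fixture(scope="session")
def logistic_550():
    """Published delayed-logistic fit at 550 W (reference truth)."""
    return LogisticParams(y_max=0.713695, k_m=0.125821, tau=10.917342)


@pytest.fixture(scope="session")
def first_order_550():
    """Published first-order fit at 550 W."""
    return FirstOrderParams(y_max=0.718277, k_m=0.073040)


@pytest.fixture(scope="session")
def global_truth_power():
    """Published generalized-model best fit for the power factor."""
    return GlobalParams(ref=759.42, k_m=0.14, tau=11.68, amplitude=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(20260929)
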