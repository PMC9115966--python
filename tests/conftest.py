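import numpy as np
import pytest

from petflux.frames import compute_weights, make_standard_schedule
from petflux.kinetics import model_tac
from petflux.simulate import DEFAULT_2C3K, DEFAULT_AIF


@pytest.fixture(scope="session")
def schedule():
    return make_standard_schedule()


@pytest.fixture(scope="session")
def aif_params():
    return DEFAULT_AIF


@pytest.fixture(scope="session")
def params_2c3k():
    return dict(DEFAULT_2C3K)


@pytest.fixture(scope="session")
def noiseless_tac(schedule, aif_params, params_2c3k):
    return model_tac("2C3K", params_2c3k, aif_params, schedule)


@pytest.fixture(scope="session")
def tac_weights(schedule, noiseless_tac):
    return compute_weights(schedule, noiseless_tac.values)
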