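import numpy as np
import pytest

from codep.neurons import NeuronParams
from codep.plasticity import ESPParams, ISPParams


@pytest.fixture
def neuron_params():
    return NeuronParams()


@pytest.fixture
def adaptive_params():
    return NeuronParams(threshold_mode="adaptive", u_reset=-60.0,
                        u_th_0=-50.0, u_th_star=20.0, tau_th=5.0)


@pytest.fixture
def esp_params():
    return ESPParams()


@pytest.fixture
def isp_params():
    return ISPParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
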