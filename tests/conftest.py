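import numpy as np
import pytest

from spindlesim.config import RunConfig
from spindlesim.neurons import IzhikevichParams, NeuronConfig, calibrate_gain


@pytest.fixture(scope="session")
def gain():
    """Calibrated rate->current map for the default Class-1 neuron."""
    return calibrate_gain(IzhikevichParams(), (0.0, 300.0))


@pytest.fixture(scope="session")
def neuron_cfg(gain):
    return NeuronConfig(gain=gain)


@pytest.fixture(scope="session")
def small_config(gain):
    """Default physics with small populations for fast protocol runs."""
    cfg = RunConfig.default()
    cfg.n_ia = cfg.n_ii = 16
    cfg._gain = gain
    return cfg
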