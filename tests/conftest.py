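import numpy as np
import pytest

from msodev.stdp_model import ModelParams, STDPKernel, init_neuron


@pytest.fixture(scope="session")
def params():
    return ModelParams()


@pytest.fixture(scope="session")
def kernel():
    return STDPKernel()


@pytest.fixture()
def quiet_params():
    """Deterministic neuron construction: no latency or activation jitter."""
    return ModelParams(l_SD=0.0, phi_low=0.0, phi_high=0.0, t_SD=0.0)


@pytest.fixture()
def default_neuron(params):
    return init_neuron(1.8, params, seed=42)
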