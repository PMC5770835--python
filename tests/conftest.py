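import numpy as np
import pytest

from exactlif import ModelParameters, build_lif_exp_system


@pytest.fixture
def params():
    """Reference parameters: tau=10 ms, C=250 pF, tau_s=2 ms, theta=20 mV."""
    return ModelParameters()


@pytest.fixture
def params_375(params):
    """Subrheobase drive I_e = 375 pA (rheobase is 500 pA)."""
    return params.replace(I_e=375.0)


@pytest.fixture
def params_600(params):
    """Suprarheobase drive I_e = 600 pA."""
    return params.replace(I_e=600.0)


@pytest.fixture
def system(params):
    return build_lif_exp_system(params)


@pytest.fixture
def system_375(params_375):
    return build_lif_exp_system(params_375)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
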