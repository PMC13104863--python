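import numpy as np
import pytest

from eusim.gompertz import Allele, GompertzParams, MappingConfig


@pytest.fixture
def vitality():
    return Allele("vitality", V=1000.0, L=9.0, dominant=True)


@pytest.fixture
def longevity():
    return Allele("longevity", V=900.0, L=10.0)


@pytest.fixture
def mapping():
    return MappingConfig(alpha_ref=0.005, V_ref=1000.0)


@pytest.fixture
def fig1_params():
    # hazard-curve illustration parameters: alpha=0.125, beta=0.15
    return GompertzParams(alpha=0.125, beta=0.15, gamma=0.0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
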