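import numpy as np
import pytest

from sln.lif import LifParams, SlnRuleParams, UpDownConfig
from sln.sif import SifNeuronParams, SifPlasticityParams, VolleyConfig


@pytest.fixture
def sif_defaults():
    """Published defaults of the model without leak."""
    return VolleyConfig(), SifNeuronParams(), SifPlasticityParams()


@pytest.fixture
def lif_defaults():
    """Published defaults of the model with leak."""
    return LifParams(), UpDownConfig(), SlnRuleParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
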