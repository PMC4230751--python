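import numpy as np
import pytest

from cablepsd import DEFAULT_PARAMS, InputEnsembleSpec, dimensionless_map


@pytest.fixture
def params():
    return DEFAULT_PARAMS


@pytest.fixture
def point100(params):
    """Dimensionless point at 100 Hz for the default neuron."""
    return dimensionless_map(params, 100.0)


@pytest.fixture
def white_ensemble():
    """Default uncorrelated white-noise ensemble: 2 um^-2, 1 fA^2/Hz."""
    return InputEnsembleSpec(n_d=2e12, n_s=2e12, coherence=0.0, input_psd=1e-30)


@pytest.fixture
def rng():
    return np.random.default_rng(20140913)
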