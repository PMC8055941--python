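import numpy as np
import pytest

from anesthnet.synthetic import build_condition_models, default_scenario
from anesthnet.types import MVARModel


@pytest.fixture(scope="session")
def scenario():
    return default_scenario(seed=0)


@pytest.fixture(scope="session")
def condition_models(scenario):
    return build_condition_models(scenario)


@pytest.fixture()
def oscillator_2ch():
    """2-channel order-2 model: 10 Hz oscillator on ch0 coupled into ch1."""
    coeffs = np.zeros((2, 2, 2))
    w = 2 * np.pi * 10.0 / 256.0
    coeffs[0, 0, 0], coeffs[1, 0, 0] = 2 * 0.95 * np.cos(w), -0.95**2
    coeffs[0, 1, 1], coeffs[1, 1, 1] = 0.5, -0.25
    coeffs[0, 1, 0] = 0.4
    return MVARModel(coefficients=coeffs, innovation_cov=np.eye(2), fs=256.0)
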