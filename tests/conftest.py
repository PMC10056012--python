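import numpy as np
import pytest

from dysfrna import load_default_model
from dysfrna.simulate import SimConfig


@pytest.fixture(scope="session")
def model():
    return load_default_model()


@pytest.fixture()
def cfg():
    return SimConfig(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(11)
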