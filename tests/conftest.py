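import numpy as np
import pytest

from dstn import SensoryParams, TuningBank


@pytest.fixture
def bank():
    return TuningBank()


@pytest.fixture
def params():
    return SensoryParams()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
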