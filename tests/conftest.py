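import numpy as np
import pytest

from netevo import parse


@pytest.fixture
def rng():
    return np.random.default_rng(20240905)


@pytest.fixture
def pa_program():
    return parse("k'")


@pytest.fixture
def er_program():
    return parse("1.0")
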