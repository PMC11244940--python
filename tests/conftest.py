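import numpy as np
import pytest

from parasyn.patterns import make_fixture


@pytest.fixture
def xor4():
    return make_fixture("xor4")


@pytest.fixture
def sep2():
    return make_fixture("sep2")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
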