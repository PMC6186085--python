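import numpy as np
import pytest

from p53netval import toy_p53_network


@pytest.fixture
def toy_net():
    return toy_p53_network()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
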