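import numpy as np
import pytest

from actihf.types import HF_LEFT, HF_RIGHT


@pytest.fixture
def rng():
    return np.random.default_rng(20150601)


@pytest.fixture
def left():
    return HF_LEFT


@pytest.fixture
def right():
    return HF_RIGHT
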