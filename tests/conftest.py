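import numpy as np
import pytest

from qeeg import QExpParams


@pytest.fixture
def fig1_params() -> QExpParams:
    """The published worked-example parameter set of the q-exponential."""
    return QExpParams(b=0.14, c=2.24, h=1.07, q=1.22)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
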