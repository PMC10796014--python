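import numpy as np
import pytest

from chitosim import PaSequence


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def d_polymer():
    """Polyglucosamine starting material for N-acetylation runs."""
    return PaSequence("D" * 1000)
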