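import numpy as np
import pytest

from repunitsim.timeline import Periodization, Phase


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def iron_age_periodization():
    """Three contiguous phases over [-800, -300)."""
    return Periodization(
        [
            Phase("I", -800, -620),
            Phase("II", -620, -450),
            Phase("III", -450, -300),
        ],
        require_contiguous=True,
    )
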