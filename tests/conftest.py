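import numpy as np
import pytest

from reactiven import GameParameters


@pytest.fixture
def donation() -> GameParameters:
    """Standard donation game used throughout: benefit 1, cost 0.5."""
    return GameParameters.donation(1.0, 0.5)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
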