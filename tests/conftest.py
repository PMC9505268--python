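import numpy as np
import pytest

from texcomplex.colorspaces import ChannelImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_rgb(rng):
    """A small random sRGB image."""
    return rng.uniform(size=(12, 16, 3))


@pytest.fixture
def random_channel(rng):
    """A seeded random intensity channel."""
    return ChannelImage(rng.uniform(size=(16, 16)), "Int", "intensity")
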