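import numpy as np
import pytest

from ringtex.io_roi import QuantizedPatch


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_patch(rng, shape=(10, 10), L=256) -> QuantizedPatch:
    return QuantizedPatch(rng.integers(0, L, shape), L)


@pytest.fixture
def patch10(rng) -> QuantizedPatch:
    return random_patch(rng)
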