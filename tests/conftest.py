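import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20260401)


@pytest.fixture
def small_bank():
    """A fixed 4-item, 3-category bank with known parameters."""
    from difpower import ItemBank

    return ItemBank(
        discrimination=np.array([1.0, 0.8, 1.2, 0.6]),
        thresholds=np.array([[-1.0, 1.0], [-0.5, 0.5], [0.0, 0.8], [-1.5, -0.2]]),
    )
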