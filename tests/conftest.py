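import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def weight_samples(rng):
    """Random weights in [0, 1] for rule-application property checks."""
    return rng.uniform(0.0, 1.0, 10_000)
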