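import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_psd(rng, d, scale=1.0):
    """Random well-conditioned PSD matrix."""
    M = rng.standard_normal((d, d))
    return scale * (M @ M.T + d * np.eye(d)) / d


@pytest.fixture
def make_psd(rng):
    return lambda d, scale=1.0: random_psd(rng, d, scale)
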