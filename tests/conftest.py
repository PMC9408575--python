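import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_cluster_data(rng):
    """Two well-separated 2-D blobs, 30 points each."""
    a = rng.normal((0.0, 0.0), 0.1, size=(30, 2))
    b = rng.normal((5.0, 5.0), 0.1, size=(30, 2))
    return np.vstack([a, b])
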