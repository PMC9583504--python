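import numpy as np
import pytest

from scor import OrderedBiomarkerData


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def make_data():
    """Factory: build OrderedBiomarkerData from per-group arrays."""

    def _make(*arrays):
        return OrderedBiomarkerData(tuple(np.asarray(a, dtype=float) for a in arrays))

    return _make


@pytest.fixture
def random_data():
    """Factory for random shifted-normal ordered-group datasets."""

    def _make(rng, M=2, d=2, n=10, shift=0.7):
        groups = tuple(rng.normal(i * shift, 1.0, (n, d)) for i in range(M))
        return OrderedBiomarkerData(groups)

    return _make
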