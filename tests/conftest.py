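import numpy as np
import pytest

from quickbundles import Tractography, three_bundle_phantom


@pytest.fixture(scope="session")
def phantom():
    """The canonical 450-streamline three-bundle phantom with labels."""
    return three_bundle_phantom(seed=0)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_streamline(rng, n_points, scale=30.0):
    """A random smooth-ish polyline: cumulative sum of Gaussian steps."""
    return np.cumsum(rng.normal(scale=scale, size=(n_points, 3)), axis=0)


@pytest.fixture
def random_tractography(rng):
    def make(n, n_points=20):
        return Tractography([random_streamline(rng, n_points) for _ in range(n)])
    return make
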