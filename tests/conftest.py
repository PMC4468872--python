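import numpy as np
import pytest

from fibrilmap.profiles import LineProfile


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_profile(intensity, bin_width=2.5, label=""):
    """Wrap a plain intensity array into a LineProfile on a regular grid."""
    intensity = np.asarray(intensity, dtype=float)
    centers = bin_width * np.arange(len(intensity)) + bin_width / 2
    return LineProfile(centers, intensity, bin_width, label=label)


@pytest.fixture
def profile_factory():
    return make_profile
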