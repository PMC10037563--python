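import numpy as np
import pytest

from marrowqib import phantom
from marrowqib.io_formats import ImageVolume


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_geometry():
    """Compact tube phantom used where full 64³ resolution is unneeded."""
    return phantom.PhantomGeometry(shape=(16, 16, 64), spacing=(0.1, 0.1, 0.3))


@pytest.fixture
def wt_truth(small_geometry):
    """Noise-free truth with the wild-type section means."""
    return phantom.make_phantom_truth(
        {q: phantom.WT_SECTION_MEANS[q] for q in phantom.QIB_NAMES},
        geometry=small_geometry,
    )


def make_volume(data, spacing=(0.1, 0.1, 0.3)):
    return ImageVolume(np.asarray(data, dtype=float), spacing)
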