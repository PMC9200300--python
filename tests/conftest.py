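import numpy as np
import pytest

from mpquant.imaging_core import BinaryMask, FluorescenceImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    return FluorescenceImage(
        pixels=rng.integers(0, 256, (40, 56, 3), dtype=np.uint8), id="rand"
    )


@pytest.fixture
def random_mask(rng):
    return BinaryMask(pixels=(rng.random((40, 56)) > 0.6).astype(np.uint8))


def disk_mask(shape, center, radius):
    """Boolean raster of a digital disk."""
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - center[0]) ** 2 + (cc - center[1]) ** 2 <= radius**2
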