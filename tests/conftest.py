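import numpy as np
import pytest

from cccfp.design import build_verum_design
from cccfp.synthesis import FingerprintImage


@pytest.fixture(scope="session")
def full_design():
    """The standard six-day Verum design (288 plates)."""
    return build_verum_design(6)


def make_image(pixels, centre=None, radius=None):
    """Wrap a raw 2-D array as a FingerprintImage with a covering ROI."""
    arr = np.asarray(pixels, dtype=np.uint8)
    if centre is None:
        centre = (arr.shape[0] // 2, arr.shape[1] // 2)
    if radius is None:
        # radius large enough that ROI 0-100 covers the whole raster
        radius = int(np.ceil(np.hypot(*arr.shape))) + 1
    return FingerprintImage(pixels=arr, centre=centre, plate_radius=radius)


@pytest.fixture
def rng():
    return np.random.default_rng(20260114)
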