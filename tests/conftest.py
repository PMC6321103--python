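import numpy as np
import pytest

from blinkhp import RoiMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def interior_roi():
    """A 48x48 ROI block centred in a 64x64 frame, 8 px from every edge."""
    mask = np.zeros((64, 64), dtype=bool)
    mask[8:56, 8:56] = True
    return RoiMask(mask, pixel_size=160.0)
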