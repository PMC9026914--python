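import numpy as np
import pytest

from mitohcs.plate_io import ChannelImage, ImageKey


@pytest.fixture
def make_image():
    """Wrap a raw array (clipped to [0,1]) as a ChannelImage."""

    def _make(pixels, pixel_size_um=0.299, key=ImageKey(1, 1, 1)):
        return ChannelImage(key, np.clip(np.asarray(pixels, float), 0, 1),
                            pixel_size_um=pixel_size_um)

    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(20417)
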