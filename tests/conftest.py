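import numpy as np
import pytest

from fishpigment.imaging import MaskedImage


@pytest.fixture
def full_mask_image():
    """4x4 image with every pixel foreground, distinct colors."""
    rng = np.random.default_rng(7)
    px = rng.integers(0, 256, size=(4, 4, 3), dtype=np.uint8)
    return MaskedImage(px, np.ones((4, 4), bool), view="lateral", image_id="tiny")


def make_image(pixels, mask=None, view="lateral", image_id="img"):
    pixels = np.asarray(pixels, dtype=np.uint8)
    if mask is None:
        mask = np.ones(pixels.shape[:2], bool)
    return MaskedImage(pixels, np.asarray(mask, bool), view=view, image_id=image_id)
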