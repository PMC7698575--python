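"""Overlay and mean-image diagnostics.

Yellow pixels are re-plotted in magenta on each photograph to make the
detected pattern visible against the fish body, and per-treatment mean
images summarize the average pigmentation pattern of a dietary group.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
from skimage.transform import resize

from .imaging import MaskedImage

__all__ = ["overlay", "mean_image"]

MAGENTA = (255, 0, 255)
WHITE_FILL = (255, 255, 255)


def overlay(
    image: MaskedImage,
    yellow: np.ndarray,
    color: tuple[int, int, int] = MAGENTA,
) -> MaskedImage:
    """Recolor the yellow-mask pixels; everything else is untouched."""
    yellow = np.asarray(yellow, dtype=bool)
    if yellow.shape != image.shape:
        raise ValueError(
            f"yellow mask {yellow.shape} does not match image {image.shape}"
        )
    out = image.pixels.copy()
    out[yellow] = np.asarray(color, dtype=np.uint8)
    return MaskedImage(out, image.mask.copy(), view=image.view, image_id=image.image_id)


def mean_image(
    images: Sequence[MaskedImage],
    canvas: tuple[int, int] | None = None,
    fill: tuple[int, int, int] = WHITE_FILL,
) -> np.ndarray:
    """Per-pixel, per-channel arithmetic mean over same-view images.

    Each image has its background replaced by ``fill``, is resized
    (bilinear) to the common canvas, and the stack is averaged and
    rounded half-up to 8 bits. The default canvas is the median height
    and width over the inputs — a pragmatic stand-in for registration,
    adequate when acquisition distance was physically fixed.
    """
    if len(images) == 0:
        raise ValueError("mean_image needs at least one image")
    views = {im.view for im in images}
    if len(views) > 1:
        raise ValueError(f"mixed views in mean_image: {sorted(views)}")
    if canvas is None:
        hs = sorted(im.shape[0] for im in images)
        ws = sorted(im.shape[1] for im in images)
        canvas = (int(np.median(hs)), int(np.median(ws)))

    acc = np.zeros((canvas[0], canvas[1], 3), dtype=float)
    fill_arr = np.asarray(fill, dtype=float)
    for im in images:
        filled = im.pixels.astype(float).copy()
        filled[~im.mask] = fill_arr
        if im.shape != canvas:
            filled = resize(
                filled, (canvas[0], canvas[1], 3), order=1, preserve_range=True,
                anti_aliasing=False,
            )
        acc += filled
    mean = acc / len(images)
    return np.clip(np.floor(mean + 0.5), 0, 255).astype(np.uint8)
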