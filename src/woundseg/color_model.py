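"""Cr-channel color model.

Skin pixels cluster in a narrow band of the chroma-red (Cr) channel of the
YCbCr color space; the whole skin detector works on that single plane and on
its 256-bin histogram.  Conversion uses the full-range (JPEG/JFIF)
coefficients,

    Cr = 128 + 0.5 R - 0.4187 G - 0.0813 B,

rounded half-up to an integer in [0, 255] so that histogram bins are exact.
"""

from __future__ import annotations

import numpy as np

__all__ = ["rgb_to_cr", "cr_histogram", "CR_SKIN_BAND"]

#: Static Cr band that covers most skin pixels; used as the fallback when the
#: dynamic threshold search fails.
CR_SKIN_BAND = (135, 160)

# Full-range JPEG coefficients.  The limited-range (BT.601 "studio") variant
# would shift the skin band; the dialect is centralised here so it can be
# swapped if a data source requires it.
_CR_WEIGHTS = np.array([0.5, -0.4187, -0.0813])
_CR_OFFSET = 128.0


def rgb_to_cr(image: np.ndarray) -> np.ndarray:
    """Convert an RGB image to its integer Cr plane.

    Parameters
    ----------
    image : (H, W, 3) array
        RGB image, channel values in [0, 255].

    Returns
    -------
    (H, W) uint8 array
        Cr values, rounded half-up and clipped to [0, 255].
    """
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[-1] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {image.shape}")
    if image.shape[0] == 0 or image.shape[1] == 0:
        raise ValueError("empty image")
    cr = _CR_OFFSET + np.asarray(image, dtype=np.float64) @ _CR_WEIGHTS
    # np.floor(x + 0.5) is round-half-up; np.round would round half to even.
    return np.clip(np.floor(cr + 0.5), 0, 255).astype(np.uint8)


def cr_histogram(crmap: np.ndarray) -> np.ndarray:
    """256-bin histogram of a Cr plane.

    Returns an int64 array ``counts`` with ``counts[v]`` the number of pixels
    of Cr value ``v``; ``counts.sum()`` equals the pixel count.
    """
    crmap = np.asarray(crmap)
    if crmap.size == 0:
        raise ValueError("empty Cr map")
    return np.bincount(crmap.ravel().astype(np.int64), minlength=256)
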