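"""Contrast adjustment and resizing to the working resolution.

Angiograms arrive at arbitrary sizes (e.g. 960×1080) and with vessel
contrast that varies with the injection; every downstream stage assumes a
square float image in [0, 1] at a common size (128 by default).  The
default contrast method is a global min–max stretch; CLAHE is available
when local contrast equalization is preferred.  Aspect ratio is *not*
preserved: the square resize mirrors the common practice of forcing the
working raster regardless of the acquisition geometry.
"""

from __future__ import annotations

import numpy as np
from PIL import Image
from skimage import exposure, transform

__all__ = [
    "CONTRAST_METHODS",
    "validate_image",
    "adjust_contrast",
    "resize_to_standard",
    "load_gray",
    "save_gray",
]

CONTRAST_METHODS = ("stretch", "clahe", "none")


def validate_image(image) -> np.ndarray:
    """Check the grayscale-image contract: 2-D, finite, in [0, 1], >= 3 px."""
    arr = np.asarray(image, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got ndim={arr.ndim}")
    if arr.shape[0] < 3 or arr.shape[1] < 3:
        raise ValueError(f"image too small: {arr.shape}, need at least 3x3")
    if not np.isfinite(arr).all():
        raise ValueError("image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("image intensities must lie in [0, 1]")
    return arr


def adjust_contrast(image, method: str = "stretch") -> np.ndarray:
    """Increase vessel/background contrast.

    ``stretch`` maps the intensity range linearly onto [0, 1] (a constant
    image is returned unchanged); ``clahe`` applies contrast-limited
    adaptive histogram equalization; ``none`` is a pass-through copy.
    """
    arr = validate_image(image)
    if method == "stretch":
        lo, hi = float(arr.min()), float(arr.max())
        if hi - lo == 0.0:
            return arr.copy()
        return (arr - lo) / (hi - lo)
    if method == "clahe":
        return np.clip(exposure.equalize_adapthist(arr), 0.0, 1.0)
    if method == "none":
        return arr.copy()
    raise ValueError(
        f"unknown contrast method {method!r}; choose one of {CONTRAST_METHODS}")


def resize_to_standard(image, size: int = 128) -> np.ndarray:
    """Bilinear resize to ``size``×``size``, output clipped to [0, 1]."""
    arr = validate_image(image)
    if size < 8:
        raise ValueError(f"target size must be >= 8, got {size}")
    out = transform.resize(arr, (size, size), order=1, mode="edge",
                           anti_aliasing=False, preserve_range=True)
    return np.clip(out, 0.0, 1.0)


def load_gray(path) -> np.ndarray:
    """Read a PNG/JPEG as a [0, 1] float grayscale image."""
    with Image.open(path) as im:
        arr = np.asarray(im.convert("L"), dtype=float) / 255.0
    return arr


def save_gray(path, image) -> None:
    arr = np.round(255.0 * np.clip(np.asarray(image, float), 0.0, 1.0))
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path)
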