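"""Contrast adjustment and unsharp-mask sharpening applied before segmentation.

Both operations work in floating point and are rounded and clipped back to the
integer grid of the stated bit depth at the end, so repeated application does
not accumulate quantization error.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import gaussian_filter

__all__ = ["adjust_contrast", "sharpen", "preprocess_image"]


def _clip_to_depth(arr: np.ndarray, like: np.ndarray, bit_depth: int) -> np.ndarray:
    out = np.clip(np.rint(arr), 0, 2**bit_depth - 1)
    return out.astype(like.dtype if np.issubdtype(like.dtype, np.integer) else np.float64)


def _check_image(img: np.ndarray) -> np.ndarray:
    img = np.asarray(img)
    if img.ndim != 2 or img.size == 0:
        raise ValueError("expected a non-empty 2-D image")
    return img


def adjust_contrast(
    img: np.ndarray,
    low_fraction: float = 0.01,
    high_fraction: float = 0.01,
    bit_depth: int = 16,
) -> np.ndarray:
    """Linear histogram stretch saturating the intensity extremes.

    The ``low_fraction`` and ``1 - high_fraction`` intensity quantiles are
    mapped to 0 and the full representable maximum; everything outside clips.
    A constant image is returned unchanged (no stretch is defined).
    """
    img = _check_image(img)
    if not (0.0 <= low_fraction < 1.0 - high_fraction <= 1.0):
        raise ValueError("require 0 <= low_fraction < 1 - high_fraction <= 1")
    lo = np.quantile(img, low_fraction)
    hi = np.quantile(img, 1.0 - high_fraction)
    if hi <= lo:
        return img.copy()
    vmax = 2**bit_depth - 1
    stretched = (img.astype(np.float64) - lo) * (vmax / (hi - lo))
    return _clip_to_depth(stretched, img, bit_depth)


def sharpen(
    img: np.ndarray,
    radius: float = 1.5,
    amount: float = 0.8,
    bit_depth: int = 16,
) -> np.ndarray:
    """Unsharp masking: ``clip(img + amount * (img - gaussian_blur(img, radius)))``."""
    img = _check_image(img)
    if radius <= 0:
        raise ValueError("radius must be positive")
    if amount < 0:
        raise ValueError("amount must be nonnegative")
    if amount == 0:
        return img.copy()
    f = img.astype(np.float64)
    blurred = gaussian_filter(f, sigma=radius, mode="reflect")
    return _clip_to_depth(f + amount * (f - blurred), img, bit_depth)


def preprocess_image(
    img: np.ndarray,
    low_fraction: float = 0.01,
    high_fraction: float = 0.01,
    radius: float = 1.5,
    amount: float = 0.8,
    bit_depth: int = 16,
) -> np.ndarray:
    """Contrast stretch followed by unsharp sharpening (the pipeline default)."""
    out = adjust_contrast(img, low_fraction, high_fraction, bit_depth=bit_depth)
    return sharpen(out, radius=radius, amount=amount, bit_depth=bit_depth)
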