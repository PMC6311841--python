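"""Grayscale ROI image handling.

Images are held as 2-D float64 arrays with intensities in [0, 1]
(8-bit inputs are divided by 255, 16-bit by 65535). The correction
routines require at least 8 pixels per side.
"""

from __future__ import annotations

import os

import numpy as np
import imageio.v3 as iio

from .errors import InvalidArgumentError

MIN_SIDE = 8


def as_gray_image(pixels: np.ndarray, *, check_range: bool = True) -> np.ndarray:
    """Validate and return a [0,1] float64 grayscale image array."""
    arr = np.asarray(pixels, dtype=np.float64)
    if arr.ndim != 2:
        raise InvalidArgumentError(f"expected a 2-D array, got ndim={arr.ndim}")
    if not np.all(np.isfinite(arr)):
        raise InvalidArgumentError("image contains non-finite values")
    if check_range and (arr.min() < 0.0 or arr.max() > 1.0):
        raise InvalidArgumentError("intensities must lie in [0, 1]")
    return arr


def require_min_size(pixels: np.ndarray) -> np.ndarray:
    arr = as_gray_image(pixels)
    h, w = arr.shape
    if h < MIN_SIDE or w < MIN_SIDE:
        raise InvalidArgumentError(
            f"image {h}x{w} too small for correction (need >= {MIN_SIDE} per side)"
        )
    return arr


def load_gray(path: str | os.PathLike) -> np.ndarray:
    """Read a grayscale PNG/TIFF and normalize to [0, 1]."""
    raw = iio.imread(path)
    if raw.ndim == 3:  # collapse RGB(A) that is actually gray
        raw = raw[..., :3].mean(axis=-1)
    raw = np.asarray(raw, dtype=np.float64)
    if raw.size == 0:
        raise InvalidArgumentError(f"empty image: {path}")
    if raw.max() > 255:
        scale = 65535.0
    elif raw.max() > 1.0:
        scale = 255.0
    else:
        scale = 1.0
    return np.clip(raw / scale, 0.0, 1.0)


def save_gray(path: str | os.PathLike, pixels: np.ndarray) -> None:
    """Write a [0,1] image as 8-bit PNG, rounding v*255 to nearest."""
    arr = as_gray_image(pixels)
    iio.imwrite(path, np.rint(arr * 255.0).astype(np.uint8))


def coefficient_of_variation(values: np.ndarray) -> float:
    """std/mean of a pixel set; 0 for an empty or zero-mean set."""
    values = np.asarray(values, dtype=np.float64)
    if values.size == 0:
        return 0.0
    mean = values.mean()
    if mean == 0.0:
        return 0.0
    return float(values.std() / mean)
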