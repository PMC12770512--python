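"""Small shared helpers: rounding convention and grayscale PNG I/O.

Every integer-rounding step in the pipeline uses a single convention,
round half away from zero, so that stage outputs are reproducible and
independent of numpy's default banker's rounding.
"""

from __future__ import annotations

import os

import numpy as np
from PIL import Image

from .errors import FormatError


def round_half_away(x):
    """Round to nearest integer, halves away from zero.

    Works on scalars and arrays; returns a float array (cast at the
    call site where a dtype contract exists).
    """
    x = np.asarray(x, dtype=np.float64)
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def to_uint8(x) -> np.ndarray:
    """Round (half away from zero), clip to [0, 255] and cast to uint8."""
    return np.clip(round_half_away(x), 0, 255).astype(np.uint8)


def validate_gray(img: np.ndarray) -> np.ndarray:
    """Check the grayscale-image contract: 2-D, integer values in [0, 255]."""
    arr = np.asarray(img)
    if arr.ndim != 2:
        raise FormatError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.size == 0:
        raise FormatError("empty image")
    if arr.dtype != np.uint8:
        if np.any(arr < 0) or np.any(arr > 255):
            raise FormatError("pixel values outside [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def load_gray(path: str | os.PathLike) -> np.ndarray:
    """Load an image file as a uint8 grayscale array.

    RGB(A) files are converted with the same luma weights used by
    :func:`lungcyto.preprocess.to_grayscale`.
    """
    from .preprocess import to_grayscale  # local import to avoid a cycle

    with Image.open(path) as im:
        if im.mode in ("L", "I;16", "I"):
            arr = np.asarray(im.convert("L"))
            return arr.astype(np.uint8)
        arr = np.asarray(im.convert("RGB"))
    return to_grayscale(arr)


def save_gray(img: np.ndarray, path: str | os.PathLike) -> None:
    """Write a uint8 grayscale array as an 8-bit single-channel PNG."""
    arr = validate_gray(img)
    Image.fromarray(arr, mode="L").save(path, format="PNG")
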