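"""Seeded affine augmentation stack and model-input rescaling.

Training-time augmentation draws one random affine map per image —
rotation, independent per-axis shifts, shear, zoom and a horizontal
flip — composed about the image center, and applies it with bilinear
sampling.  Test and validation images are never augmented.  The
``rescale_to_unit`` step (divide by 255) is the only place the
pipeline leaves 8-bit intensities; it is applied at model-input time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage import transform as sktransform

from ._util import to_uint8, validate_gray
from .errors import ConfigurationError


@dataclass(frozen=True)
class AugmentConfig:
    """Augmentation ranges.

    ``zoom_range=z`` means scale drawn uniformly from ``[1-z, 1+z]``;
    ``shear_range`` is a shear-angle-equivalent range in radians;
    shifts are fractions of the image width/height, drawn per axis
    independently.
    """

    rotation_range_deg: float = 20.0
    width_shift_frac: float = 0.3
    height_shift_frac: float = 0.3
    shear_range: float = 0.2
    zoom_range: float = 0.2
    horizontal_flip: bool = True
    rescale: float = 1.0 / 255.0
    fill_mode: str = "nearest"
    seed: int = 0

    def __post_init__(self):
        for name in ("rotation_range_deg", "width_shift_frac",
                     "height_shift_frac", "shear_range", "zoom_range"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be >= 0")
        if self.rescale <= 0:
            raise ConfigurationError("rescale must be positive")
        if self.fill_mode not in ("nearest", "constant", "reflect", "wrap"):
            raise ConfigurationError(f"unknown fill_mode {self.fill_mode!r}")


@dataclass(frozen=True)
class AffineParams:
    """One sampled transform: angles in degrees, shifts in pixels."""

    rotation_deg: float = 0.0
    shift_x: float = 0.0
    shift_y: float = 0.0
    shear: float = 0.0
    zoom: float = 1.0
    flip: bool = False


def sample_transform(cfg: AugmentConfig, rng: np.random.Generator,
                     shape: tuple[int, int]) -> AffineParams:
    """Draw one set of affine parameters for an image of ``shape``."""
    h, w = shape
    return AffineParams(
        rotation_deg=rng.uniform(-cfg.rotation_range_deg, cfg.rotation_range_deg),
        shift_x=rng.uniform(-cfg.width_shift_frac, cfg.width_shift_frac) * w,
        shift_y=rng.uniform(-cfg.height_shift_frac, cfg.height_shift_frac) * h,
        shear=rng.uniform(-cfg.shear_range, cfg.shear_range),
        zoom=rng.uniform(1 - cfg.zoom_range, 1 + cfg.zoom_range),
        flip=bool(cfg.horizontal_flip and rng.random() < 0.5),
    )


def affine_matrix(params: AffineParams, shape: tuple[int, int]) -> np.ndarray:
    """Forward 3x3 affine matrix in (x, y) coordinates about the center.

    Composition order: flip, zoom, shear, rotation (about the image
    center), then translation.
    """
    h, w = shape
    cx, cy = (w - 1) / 2.0, (h - 1) / 2.0
    theta = np.deg2rad(params.rotation_deg)
    rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                    [np.sin(theta), np.cos(theta), 0],
                    [0, 0, 1]])
    shear = np.array([[1, np.tan(params.shear), 0],
                      [0, 1, 0],
                      [0, 0, 1]])
    zoom = np.diag([params.zoom, params.zoom, 1.0])
    flip = np.diag([-1.0 if params.flip else 1.0, 1.0, 1.0])
    center = np.array([[1, 0, cx], [0, 1, cy], [0, 0, 1]], dtype=float)
    uncenter = np.array([[1, 0, -cx], [0, 1, -cy], [0, 0, 1]], dtype=float)
    shift = np.array([[1, 0, params.shift_x], [0, 1, params.shift_y],
                      [0, 0, 1]], dtype=float)
    return shift @ center @ rot @ shear @ zoom @ flip @ uncenter


def apply_transform(img: np.ndarray, params: AffineParams,
                    fill_mode: str = "nearest") -> np.ndarray:
    """Warp a grayscale image by the sampled affine map.

    Bilinear sampling; border handling per ``fill_mode`` ("nearest"
    replicates edges).  Output has the input shape and stays in
    [0, 255].
    """
    img = validate_gray(img)
    m = affine_matrix(params, img.shape)
    det = np.linalg.det(m[:2, :2])
    if abs(det) < 1e-12:
        raise ConfigurationError("singular affine transform")
    inverse = sktransform.AffineTransform(matrix=np.linalg.inv(m))
    mode = {"nearest": "edge", "constant": "constant",
            "reflect": "reflect", "wrap": "wrap"}[fill_mode]
    warped = sktransform.warp(img.astype(np.float64), inverse, order=1,
                              mode=mode, cval=255.0, preserve_range=True)
    return to_uint8(warped)


def rescale_to_unit(img: np.ndarray) -> np.ndarray:
    """Map 8-bit intensities to floats in [0, 1] (divide by 255)."""
    img = validate_gray(img)
    return img.astype(np.float64) / 255.0


def augment_image(img: np.ndarray, cfg: AugmentConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Sample and apply one transform; returns an 8-bit image."""
    params = sample_transform(cfg, rng, img.shape)
    return apply_transform(img, params, cfg.fill_mode)


def identity_config() -> AugmentConfig:
    """All ranges zero and flip off: the stack is the identity map."""
    return AugmentConfig(rotation_range_deg=0, width_shift_frac=0,
                         height_shift_frac=0, shear_range=0, zoom_range=0,
                         horizontal_flip=False)
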