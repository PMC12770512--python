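"""Feature processing: dark pre-mapping, Otsu separation, cleanup,
mask composition and midtone lightening.

This stage turns an enhanced grayscale cell image into its final
training representation.  Mid-grey "fluid" regions carry boundary
information only where they touch cells, so the stage

1. pre-maps very dark pixels (<= ``dark_threshold``) to black and
   remembers them (fluid pockets must survive later masking),
2. separates tissue/fluid from the near-white background with Otsu's
   threshold (maximizing between-class variance),
3. drops connected foreground components smaller than
   ``min_object_px`` (holes are deliberately never filled: small white
   structures inside cells are features),
4. composes the final image — dark-flagged pixels black, background
   white, everything else untouched — and
5. optionally lightens midtones (``v -> min(255, round(alpha*v))``)
   to push uninformative fluid grey toward the background while
   leaving true blacks and whites fixed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._util import to_uint8, validate_gray
from .errors import ConfigurationError, InputError


@dataclass(frozen=True)
class FeatureConfig:
    """Parameters of the feature-processing stage.

    dark_threshold
        Intensity at or below which a pixel is pre-mapped to black
        (fluid pockets and dense chromatin).
    min_object_px
        Connected foreground components smaller than this many pixels
        are removed as artifacts (strictly smaller; a component of
        exactly this size is kept).
    fill_holes
        Whether to fill background holes inside foreground components.
        Off by default: intracellular white structures are features.
    alpha, beta
        Saturating affine midtone map ``min(255, alpha*v + beta)``.
    connectivity
        4 or 8 (default) pixel connectivity for component labeling.
    """

    dark_threshold: int = 60
    min_object_px: int = 30
    fill_holes: bool = False
    alpha: float = 1.3
    beta: float = 0.0
    connectivity: int = 8
    otsu_exclude_dark: bool = False

    def __post_init__(self):
        if not 0 <= self.dark_threshold <= 255:
            raise ConfigurationError("dark_threshold must be in [0, 255]")
        if self.min_object_px < 0:
            raise ConfigurationError("min_object_px must be >= 0")
        if self.alpha <= 0:
            raise ConfigurationError("alpha must be positive")
        if self.connectivity not in (4, 8):
            raise ConfigurationError("connectivity must be 4 or 8")


@dataclass(frozen=True)
class OtsuResult:
    """Selected threshold plus the full between-class variance curve.

    ``threshold`` is the smallest t maximizing
    ``w0(t) * w1(t) * (mu0(t) - mu1(t))**2`` where class 0 is
    ``{v <= t}`` and class 1 is ``{v > t}``.
    """

    threshold: int
    between_class_variance_curve: np.ndarray


def premap_dark(img: np.ndarray, cfg: FeatureConfig | None = None):
    """Set pixels at or below the dark threshold to 0 and flag them.

    Returns ``(premapped_image, dark_flag_mask)``; unflagged pixels
    are returned unchanged.
    """
    img = validate_gray(img)
    cfg = cfg or FeatureConfig()
    dark = img <= cfg.dark_threshold
    out = img.copy()
    out[dark] = 0
    return out, dark


def otsu_threshold(img: np.ndarray) -> OtsuResult:
    """Otsu's threshold by exhaustive scan over all 256 candidates.

    A single-valued image returns that value by convention (the
    variance curve is identically zero there).
    """
    arr = np.asarray(img)
    if arr.size == 0:
        raise InputError("empty image")
    arr = validate_gray(arr)
    hist = np.bincount(arr.ravel(), minlength=256).astype(np.float64)
    n = hist.sum()
    p = hist / n
    w0 = np.cumsum(p)
    w1 = 1.0 - w0
    cum_mu = np.cumsum(p * np.arange(256))
    mu_t = cum_mu[-1]
    curve = np.zeros(256)
    valid = (w0 > 0) & (w1 > 0)
    mu0 = np.divide(cum_mu, w0, out=np.zeros(256), where=valid)
    mu1 = np.divide(mu_t - cum_mu, w1, out=np.zeros(256), where=valid)
    curve[valid] = (w0 * w1 * (mu0 - mu1) ** 2)[valid]
    if not np.any(valid):  # single-valued image
        return OtsuResult(int(arr.flat[0]), curve)
    return OtsuResult(int(np.argmax(curve)), curve)


def binarize_foreground(img: np.ndarray, threshold: int) -> np.ndarray:
    """Foreground mask: pixels at or below the threshold.

    Tissue and fluid are darker than the near-white background, so the
    at-or-below class is the foreground.
    """
    img = validate_gray(img)
    if not 0 <= threshold <= 255:
        raise InputError(f"threshold {threshold} outside [0, 255]")
    return img <= threshold


def _structure(connectivity: int) -> np.ndarray:
    return ndimage.generate_binary_structure(2, 2 if connectivity == 8 else 1)


def remove_small_components(mask: np.ndarray,
                            cfg: FeatureConfig | None = None) -> np.ndarray:
    """Remove connected components strictly smaller than ``min_object_px``.

    Components of exactly the minimum size are retained verbatim.
    Background holes are filled only if ``fill_holes`` is set (off by
    default).
    """
    mask = np.asarray(mask, dtype=bool)
    cfg = cfg or FeatureConfig()
    structure = _structure(cfg.connectivity)
    labels, n = ndimage.label(mask, structure=structure)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= cfg.min_object_px
    keep[0] = False
    out = keep[labels]
    if cfg.fill_holes:
        out = ndimage.binary_fill_holes(out, structure=structure)
    return out


def compose_final(enhanced: np.ndarray, fg: np.ndarray,
                  dark: np.ndarray) -> np.ndarray:
    """Three-way composition, evaluated in priority order.

    dark-flagged pixel -> 0 (fluid pockets stay black); else
    non-foreground -> 255 (background masked to white); else the
    enhanced grey value passes through.
    """
    enhanced = validate_gray(enhanced)
    fg = np.asarray(fg, dtype=bool)
    dark = np.asarray(dark, dtype=bool)
    if fg.shape != enhanced.shape or dark.shape != enhanced.shape:
        raise InputError(
            f"shape mismatch: image {enhanced.shape}, fg {fg.shape}, dark {dark.shape}"
        )
    out = enhanced.copy()
    out[~fg] = 255
    out[dark] = 0
    return out


def midtone_lighten(img: np.ndarray, cfg: FeatureConfig | None = None) -> np.ndarray:
    """Saturating affine brightening ``min(255, round(alpha*v + beta))``.

    With the default alpha=1.3 this leaves 0 and 255 fixed, brightens
    midtones (100 -> 130) and pushes high greys into the white
    background (200 -> 255).
    """
    img = validate_gray(img)
    cfg = cfg or FeatureConfig()
    return to_uint8(cfg.alpha * img.astype(np.float64) + cfg.beta)


def extract_features(img: np.ndarray, cfg: FeatureConfig | None = None):
    """Run the full feature-processing chain on an enhanced image.

    Returns ``(final_image, fg_mask, dark_mask, otsu)`` where the
    foreground mask is the size-filtered Otsu foreground and
    ``final_image`` is the three-way composition (not yet lightened).
    """
    img = validate_gray(img)
    cfg = cfg or FeatureConfig()
    premapped, dark = premap_dark(img, cfg)
    if cfg.otsu_exclude_dark:
        vals = premapped[~dark]
        otsu = otsu_threshold(vals.reshape(1, -1)) if vals.size else otsu_threshold(premapped)
    else:
        otsu = otsu_threshold(premapped)
    fg = binarize_foreground(premapped, otsu.threshold)
    fg = remove_small_components(fg, cfg)
    final = compose_final(img, fg, dark)
    return final, fg, dark, otsu


def quality_metrics(before: np.ndarray, after: np.ndarray,
                    fg: np.ndarray, dark: np.ndarray) -> dict:
    """Enhancement quality report on a before/after image pair.

    SNR proxy: ``|mean(fg) - mean(bg)| / std(bg)`` with bg the
    non-foreground region, evaluated separately on the before and the
    after image.  A constant background in the *before* image makes
    the baseline undefined (reported as None).  A constant background
    in the *after* image with a nonzero class separation is the ideal
    limit of background suppression and reports infinity.

    Midtone contrast: standard deviation over the pixels whose
    *before* value lies in [100, 180], on each image.

    Relative changes are ``after/before - 1`` (None when a side is
    undefined; infinite when the after-side SNR is infinite).
    """
    before = validate_gray(before)
    after = validate_gray(after)
    fg = np.asarray(fg, dtype=bool)
    dark = np.asarray(dark, dtype=bool)
    if before.shape != after.shape or fg.shape != before.shape:
        raise InputError("shape mismatch between images and masks")
    bg = ~fg

    def _snr(img: np.ndarray, baseline: bool):
        if not bg.any() or not fg.any():
            return None
        sep = abs(float(img[fg].mean()) - float(img[bg].mean()))
        spread = float(img[bg].std())
        if spread == 0:
            if baseline or sep == 0:
                return None
            return float("inf")
        return sep / spread

    snr_before = _snr(before, baseline=True)
    snr_after = _snr(after, baseline=False)

    mid = (before >= 100) & (before <= 180)
    contrast_before = float(before[mid].std()) if mid.any() else None
    contrast_after = float(after[mid].std()) if mid.any() else None

    def _rel(a, b):
        if a is None or b is None or b == 0:
            return None
        if a == float("inf"):
            return float("inf")
        return a / b - 1.0

    return {
        "snr_before": snr_before,
        "snr_after": snr_after,
        "snr_relative_change": _rel(snr_after, snr_before),
        "midtone_contrast_before": contrast_before,
        "midtone_contrast_after": contrast_after,
        "midtone_contrast_relative_change": _rel(contrast_after, contrast_before),
    }
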