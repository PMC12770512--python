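"""Image standardization and enhancement.

The stages here bring every input cell image onto a common footing
before feature processing: grayscale conversion, bilinear resizing to
the model input size, contrast-limited adaptive histogram equalization
(CLAHE) and 3x3 median denoising.  All stages operate on 8-bit
intensities in [0, 255]; rescaling to [0, 1] happens only at model
input time (see :mod:`lungcyto.augment`).

CLAHE here follows the classic tile scheme: the image is divided into
a grid of tiles, each tile's histogram is clipped at
``clip_limit * tile_pixels / 256`` with the excess mass redistributed
uniformly over all bins, an equalization mapping is derived per tile,
and per-pixel output values are bilinearly interpolated between the
mappings of the four surrounding tile centers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from ._util import to_uint8, validate_gray
from .errors import ConfigurationError, FormatError

#: ITU-R BT.601 luma weights used for RGB -> grayscale conversion.
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


@dataclass(frozen=True)
class ClaheConfig:
    """CLAHE parameters.

    clip_limit
        Histogram clip limit as a multiple of the uniform bin height
        ``tile_pixels / 256``.  Higher values allow stronger local
        contrast amplification.
    tile_grid
        Number of tile rows and columns the image is divided into.
    """

    clip_limit: float = 2.0
    tile_grid: tuple[int, int] = (8, 8)

    def __post_init__(self):
        if self.clip_limit <= 0:
            raise ConfigurationError("clip_limit must be positive")
        rows, cols = self.tile_grid
        if rows < 1 or cols < 1:
            raise ConfigurationError("tile_grid counts must be >= 1")


def to_grayscale(image: np.ndarray) -> np.ndarray:
    """Convert a 1- or 3-channel image to a single-channel uint8 image.

    Three-channel input is reduced with the BT.601 luma weights
    0.299/0.587/0.114 and rounded half away from zero; grayscale input
    is returned unchanged (as uint8).
    """
    arr = np.asarray(image)
    if arr.ndim == 2:
        return validate_gray(arr)
    if arr.ndim == 3 and arr.shape[2] == 1:
        return validate_gray(arr[:, :, 0])
    if arr.ndim == 3 and arr.shape[2] == 3:
        w = np.asarray(LUMA_WEIGHTS)
        luma = arr.astype(np.float64) @ w
        return to_uint8(luma)
    raise FormatError(f"expected 1 or 3 channels, got shape {arr.shape}")


def resize_image(img: np.ndarray, target: tuple[int, int] = (224, 224)) -> np.ndarray:
    """Resize a grayscale image to ``target = (height, width)``.

    Bilinear interpolation on the align-corners grid (output corner
    pixels sample input corner pixels exactly), rounded half away from
    zero.  Returns a copy of the input when it already has the target
    size, so the operation is an exact identity there.
    """
    img = validate_gray(img)
    th, tw = int(target[0]), int(target[1])
    if th <= 0 or tw <= 0:
        raise ConfigurationError(f"invalid target size {target!r}")
    h, w = img.shape
    if (h, w) == (th, tw):
        return img.copy()

    def _coords(n_src: int, n_dst: int) -> np.ndarray:
        if n_dst == 1:
            return np.array([(n_src - 1) / 2.0])
        return np.arange(n_dst) * (n_src - 1) / (n_dst - 1)

    ys = _coords(h, th)
    xs = _coords(w, tw)
    y0 = np.floor(ys).astype(int)
    x0 = np.floor(xs).astype(int)
    y1 = np.minimum(y0 + 1, h - 1)
    x1 = np.minimum(x0 + 1, w - 1)
    fy = (ys - y0)[:, None]
    fx = (xs - x0)[None, :]
    im = img.astype(np.float64)
    top = im[np.ix_(y0, x0)] * (1 - fx) + im[np.ix_(y0, x1)] * fx
    bot = im[np.ix_(y1, x0)] * (1 - fx) + im[np.ix_(y1, x1)] * fx
    return to_uint8(top * (1 - fy) + bot * fy)


def clip_histogram(hist: np.ndarray, limit: float) -> np.ndarray:
    """Clip a 256-bin histogram at ``limit`` and redistribute the excess
    uniformly over all bins.  Total mass is conserved exactly.
    """
    hist = np.asarray(hist, dtype=np.float64)
    clipped = np.minimum(hist, limit)
    excess = hist.sum() - clipped.sum()
    return clipped + excess / hist.size


def _tile_mapping(tile: np.ndarray, clip_limit: float) -> np.ndarray:
    """Equalization lookup table (256 entries) for one tile.

    The mapping sends the lowest occupied intensity to 0 and the
    highest to 255 via the clipped cumulative histogram.  A
    single-valued tile gets the identity mapping so constant regions
    stay constant.
    """
    n = tile.size
    hist = np.bincount(tile.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) <= 1:
        return np.arange(256, dtype=np.float64)
    limit = clip_limit * n / 256.0
    hist = clip_histogram(hist, limit)
    cdf = np.cumsum(hist)
    cdf_min = cdf[np.nonzero(hist)[0][0]]
    denom = n - cdf_min
    if denom <= 0:  # pathological: all mass in the first occupied bin
        return np.arange(256, dtype=np.float64)
    return 255.0 * np.clip(cdf - cdf_min, 0, None) / denom


def apply_clahe(img: np.ndarray, cfg: ClaheConfig | None = None) -> np.ndarray:
    """Contrast-limited adaptive histogram equalization.

    Per-tile mappings are computed as in :func:`_tile_mapping` and the
    output value of each pixel is the bilinear interpolation of the
    mappings of its four neighboring tile centers (clamped at the
    image border, so corner regions use a single tile's mapping).
    """
    img = validate_gray(img)
    cfg = cfg or ClaheConfig()
    rows, cols = cfg.tile_grid
    h, w = img.shape
    if h < rows or w < cols:
        raise ConfigurationError(
            f"image {img.shape} smaller than tile grid {cfg.tile_grid}"
        )

    y_edges = [round(i * h / rows) for i in range(rows + 1)]
    x_edges = [round(j * w / cols) for j in range(cols + 1)]
    luts = np.empty((rows, cols, 256), dtype=np.float64)
    for i in range(rows):
        for j in range(cols):
            tile = img[y_edges[i]:y_edges[i + 1], x_edges[j]:x_edges[j + 1]]
            luts[i, j] = _tile_mapping(tile, cfg.clip_limit)

    cy = np.array([(y_edges[i] + y_edges[i + 1] - 1) / 2.0 for i in range(rows)])
    cx = np.array([(x_edges[j] + x_edges[j + 1] - 1) / 2.0 for j in range(cols)])

    def _interp_axis(coords: np.ndarray, centers: np.ndarray):
        """Lower tile index and fractional weight per pixel coordinate."""
        i0 = np.clip(np.searchsorted(centers, coords, side="right") - 1, 0,
                     len(centers) - 1)
        i1 = np.minimum(i0 + 1, len(centers) - 1)
        span = centers[i1] - centers[i0]
        frac = np.where(span > 0, (coords - centers[i0]) / np.where(span > 0, span, 1),
                        0.0)
        frac = np.clip(frac, 0.0, 1.0)
        return i0, i1, frac

    yy = np.arange(h, dtype=np.float64)
    xx = np.arange(w, dtype=np.float64)
    iy0, iy1, fy = _interp_axis(yy, cy)
    ix0, ix1, fx = _interp_axis(xx, cx)

    iy0 = iy0[:, None]
    iy1 = iy1[:, None]
    fy = fy[:, None]
    ix0 = ix0[None, :]
    ix1 = ix1[None, :]
    fx = fx[None, :]

    v00 = luts[iy0, ix0, img]
    v01 = luts[iy0, ix1, img]
    v10 = luts[iy1, ix0, img]
    v11 = luts[iy1, ix1, img]
    out = (v00 * (1 - fy) * (1 - fx) + v01 * (1 - fy) * fx
           + v10 * fy * (1 - fx) + v11 * fy * fx)
    return to_uint8(out)


def global_hist_equalize(img: np.ndarray) -> np.ndarray:
    """Plain global histogram equalization (no clipping, no tiles).

    Uses the same mapping convention as the CLAHE tiles; provided as a
    reference point — CLAHE with a 1x1 grid and an unbounded clip
    limit reduces to this.
    """
    img = validate_gray(img)
    lut = _tile_mapping(img, clip_limit=np.inf)
    return to_uint8(lut[img])


def median_denoise(img: np.ndarray, kernel: int = 3) -> np.ndarray:
    """Median filter with an odd ``kernel x kernel`` window.

    Borders are handled by edge replication.  The default 3x3 window
    removes salt-and-pepper impulses while preserving cell boundaries.
    """
    img = validate_gray(img)
    if kernel % 2 == 0 or kernel < 3:
        raise ConfigurationError("kernel must be odd and >= 3")
    return ndimage.median_filter(img, size=kernel, mode="nearest")


def preprocess_image(
    image: np.ndarray,
    target: tuple[int, int] = (224, 224),
    clahe: ClaheConfig | None = None,
    kernel: int = 3,
) -> np.ndarray:
    """Full standardization chain: grayscale -> resize -> CLAHE -> median."""
    gray = to_grayscale(image)
    resized = resize_image(gray, target)
    enhanced = apply_clahe(resized, clahe)
    return median_denoise(enhanced, kernel)
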