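"""Synthetic single-cell microscopy images for the three lung cancer
subtypes.

Real cytology images of this kind show dark nuclear material (low
intensities), mid-grey cellular fluid, and a near-white slide
background, with subtype-specific arrangements of the dark material:

* adenocarcinoma — glandular lumina: a thin dark ring of nuclei
  around a clear (light) lumen;
* neuroendocrine carcinoma — rosettes: clusters of small dark nuclei
  arranged around common centers;
* squamous cell carcinoma — keratin pearls: concentric dark annuli
  around a keratinized mid-grey core.

The generator draws these motifs as hard (non-anti-aliased) discs and
annuli with integer intensities so that thresholding behavior
downstream is exactly predictable, adds salt-and-pepper sensor noise
and a mild linear illumination gradient, and writes 8-bit grayscale
PNGs plus a CSV manifest.  Per-image fluid intensities cluster around
a per-image mean in the low-to-mid 100s (tissue-level homogeneity),
which places per-image Otsu thresholds in the range seen on real
denoised cytology material.

Structure radii are specified at the default 224x224 scale and scale
linearly with image size, so small desk-scale images keep the same
class geometry.
"""

from __future__ import annotations

import hashlib
import os
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._util import round_half_away, save_gray
from .errors import ConfigurationError

CLASS_NAMES = ("adenocarcinoma", "neuroendocrine", "squamous")

#: Image counts per class as collected in the source hospital cohort.
HOSPITAL_CLASS_COUNTS = {
    "adenocarcinoma": 1537,
    "neuroendocrine": 1573,
    "squamous": 1540,
}


@dataclass(frozen=True)
class SynthConfig:
    """Generator parameters.

    Intensity intervals are inclusive ``(low, high)`` pairs on the
    0-255 scale.  ``noise_fraction`` is the probability that a pixel
    is replaced by an exact 0 or 255 impulse; ``illumination_amplitude``
    is the maximum additive magnitude of the linear shading gradient.
    """

    per_class_count: int = 20
    image_size: tuple[int, int] = (224, 224)
    background_range: tuple[int, int] = (230, 255)
    nucleus_range: tuple[int, int] = (10, 60)
    fluid_range: tuple[int, int] = (100, 180)
    noise_fraction: float = 0.01
    illumination_amplitude: float = 10.0
    seed: int = 0

    def __post_init__(self):
        for name in ("background_range", "nucleus_range", "fluid_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 255):
                raise ConfigurationError(f"{name}={lo, hi} must be a non-empty "
                                         "interval within [0, 255]")
        if not 0 <= self.noise_fraction <= 0.2:
            raise ConfigurationError("noise_fraction must be in [0, 0.2]")
        if self.per_class_count < 0:
            raise ConfigurationError("per_class_count must be >= 0")
        h, w = self.image_size
        if h < 8 or w < 8:
            raise ConfigurationError("image_size must be at least 8x8")
        if self.illumination_amplitude < 0:
            raise ConfigurationError("illumination_amplitude must be >= 0")


@dataclass(frozen=True)
class ClassMotif:
    """Geometric recipe for one subtype's dark-material arrangement.

    Radii and thicknesses are in pixels at the reference 224x224
    scale.  ``kind`` selects the renderer: ``ring`` (one thin annulus,
    glandular lumen), ``rosette`` (clusters of small discs) or
    ``pearl`` (concentric annuli around a mid-grey core).
    """

    name: str
    kind: str
    ring_radius: tuple[float, float] = (28.0, 34.0)
    ring_thickness: float = 4.5
    disc_radius: tuple[float, float] = (3.0, 4.0)
    discs_per_rosette: int = 8
    rosette_ring_radius: tuple[float, float] = (7.0, 10.0)
    n_rosettes: int = 3
    rosette_spread: float = 0.06
    pearl_radii: tuple[float, ...] = (10.0, 18.0, 26.0)
    pearl_thickness: float = 3.0

    def __post_init__(self):
        if self.kind not in ("ring", "rosette", "pearl"):
            raise ConfigurationError(f"unknown motif kind {self.kind!r}")


#: Default motifs for the three subtypes.
MOTIFS = {
    "adenocarcinoma": ClassMotif("adenocarcinoma", "ring"),
    "neuroendocrine": ClassMotif("neuroendocrine", "rosette"),
    "squamous": ClassMotif("squamous", "pearl"),
}

_REFERENCE_SIZE = 224.0


def _disc_mask(shape, cy, cx, r):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    return (yy - cy) ** 2 + (xx - cx) ** 2 <= r * r


def _annulus_mask(shape, cy, cx, r_outer, thickness):
    yy, xx = np.ogrid[: shape[0], : shape[1]]
    d2 = (yy - cy) ** 2 + (xx - cx) ** 2
    r_in = max(r_outer - thickness, 0.0)
    return (d2 <= r_outer * r_outer) & (d2 > r_in * r_in)


def _fluid_intensity(cfg: SynthConfig, base: float, rng) -> int:
    lo, hi = cfg.fluid_range
    v = base + rng.uniform(-8, 8)
    return int(np.clip(round_half_away(v), lo, hi))


def generate_image(motif: ClassMotif | None, config: SynthConfig,
                   rng: np.random.Generator) -> np.ndarray:
    """Render one synthetic cell image.

    Scene order: constant background, fluid blobs, the class motif
    (dark nuclear material), then the illumination gradient (optics)
    and finally salt-and-pepper impulses (sensor), so noise pixels are
    exact 0/255 in the output.  ``motif=None`` draws no structures at
    all (background-only degenerate case).
    """
    h, w = config.image_size
    scale = min(h, w) / _REFERENCE_SIZE
    nlo, nhi = config.nucleus_range

    bg = int(rng.integers(config.background_range[0],
                          config.background_range[1] + 1))
    img = np.full((h, w), bg, dtype=np.float64)

    if motif is None:
        return _finish_image(img, config, rng)

    # Fluid blobs: mid-grey discs clustered around a per-image mean in
    # the lower half of the fluid range.
    flo, fhi = config.fluid_range
    fluid_base = rng.uniform(flo + 5, flo + 0.4 * (fhi - flo))
    n_blobs = int(rng.integers(5, 8))
    for _ in range(n_blobs):
        r = rng.uniform(15, 24) * scale
        cy = rng.uniform(r, h - r)
        cx = rng.uniform(r, w - r)
        img[_disc_mask((h, w), cy, cx, r)] = _fluid_intensity(config, fluid_base, rng)

    # Class motif around a jittered center.
    margin = 0.30
    cy0 = h / 2 + rng.uniform(-margin * h / 2, margin * h / 2)
    cx0 = w / 2 + rng.uniform(-margin * w / 2, margin * w / 2)

    def _nucleus_value():
        return int(rng.integers(nlo, nhi + 1))

    if motif.kind == "ring":
        r = rng.uniform(*motif.ring_radius) * scale
        img[_annulus_mask((h, w), cy0, cx0, r,
                          max(motif.ring_thickness * scale, 1.5))] = _nucleus_value()
    elif motif.kind == "rosette":
        for _ in range(motif.n_rosettes):
            rcy = cy0 + rng.uniform(-motif.rosette_spread, motif.rosette_spread) * h
            rcx = cx0 + rng.uniform(-motif.rosette_spread, motif.rosette_spread) * w
            ring_r = rng.uniform(*motif.rosette_ring_radius) * scale
            phase = rng.uniform(0, 2 * np.pi)
            disc_r = max(rng.uniform(*motif.disc_radius) * scale, 1.0)
            for k in range(motif.discs_per_rosette):
                ang = phase + 2 * np.pi * k / motif.discs_per_rosette
                img[_disc_mask((h, w), rcy + ring_r * np.sin(ang),
                               rcx + ring_r * np.cos(ang), disc_r)] = _nucleus_value()
    else:  # pearl
        core_r = max(motif.pearl_radii) * scale
        img[_disc_mask((h, w), cy0, cx0, core_r)] = _fluid_intensity(
            config, fluid_base, rng)
        for pr in motif.pearl_radii:
            img[_annulus_mask((h, w), cy0, cx0, pr * scale,
                              max(motif.pearl_thickness * scale, 1.5))] = _nucleus_value()

    # A few stray nuclei for texture.
    for _ in range(3):
        r = max(2.0 * scale, 1.0)
        img[_disc_mask((h, w), rng.uniform(0, h), rng.uniform(0, w),
                       r)] = _nucleus_value()

    return _finish_image(img, config, rng)


def _finish_image(img: np.ndarray, config: SynthConfig,
                  rng: np.random.Generator) -> np.ndarray:
    """Apply the acquisition chain: illumination, then impulse noise."""
    h, w = img.shape
    # Illumination gradient (optics), clipped to the valid range.
    if config.illumination_amplitude > 0:
        theta = rng.uniform(0, 2 * np.pi)
        amp = rng.uniform(0, config.illumination_amplitude)
        yy, xx = np.mgrid[:h, :w]
        proj = (np.cos(theta) * (xx - w / 2) + np.sin(theta) * (yy - h / 2))
        denom = max(np.abs(proj).max(), 1.0)
        img = img + amp * proj / denom

    img = np.clip(round_half_away(img), 0, 255)

    # Sensor impulse noise: exact 0 or 255, applied last.
    if config.noise_fraction > 0:
        hit = rng.random((h, w)) < config.noise_fraction
        salt = rng.random((h, w)) < 0.5
        img[hit & salt] = 255
        img[hit & ~salt] = 0

    return img.astype(np.uint8)


def generate_dataset(config: SynthConfig, out_dir: str | os.PathLike,
                     class_counts: dict[str, int] | None = None) -> pd.DataFrame:
    """Generate a balanced dataset on disk and return its manifest.

    One 8-bit grayscale PNG per sample under ``out_dir/<class>/``;
    the manifest (also written to ``out_dir/manifest.csv``) has
    columns ``path,label,split,fold`` with split/fold unassigned.
    Generation is bit-reproducible for a fixed config.
    """
    out_dir = Path(out_dir)
    if class_counts is None:
        class_counts = {name: config.per_class_count for name in CLASS_NAMES}
    for name in class_counts:
        if name not in MOTIFS:
            raise ConfigurationError(f"unknown class {name!r}")
        if class_counts[name] < 0:
            raise ConfigurationError("class counts must be >= 0")

    rows = []
    rng = np.random.default_rng(config.seed)
    for name in CLASS_NAMES:
        count = class_counts.get(name, 0)
        if count == 0:
            continue
        class_dir = out_dir / name
        class_dir.mkdir(parents=True, exist_ok=True)
        for i in range(count):
            img = generate_image(MOTIFS[name], config, rng)
            path = class_dir / f"{name}_{i:05d}.png"
            save_gray(img, path)
            rows.append({"path": str(path), "label": name,
                         "split": "", "fold": pd.NA})
    manifest = pd.DataFrame(rows, columns=["path", "label", "split", "fold"])
    manifest["fold"] = manifest["fold"].astype("Int64")
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return manifest


def generate_arrays(config: SynthConfig,
                    class_counts: dict[str, int] | None = None):
    """In-memory variant of :func:`generate_dataset`.

    Returns ``(images, labels)`` with the same per-class ordering and
    the same RNG stream as the on-disk generator, for tests and
    desk-scale training that skip the filesystem.
    """
    if class_counts is None:
        class_counts = {name: config.per_class_count for name in CLASS_NAMES}
    images, labels = [], []
    rng = np.random.default_rng(config.seed)
    for name in CLASS_NAMES:
        for _ in range(class_counts.get(name, 0)):
            images.append(generate_image(MOTIFS[name], config, rng))
            labels.append(name)
    return images, labels


def radial_profile(img: np.ndarray, dark_threshold: int = 60,
                   n_bins: int = 16) -> np.ndarray:
    """Normalized histogram of dark-pixel distances from their centroid.

    The profile is translation-invariant (distances are measured from
    the dark-pixel centroid) and separates the three motif geometries:
    a thin shell (lumen ring), compact clustered mass (rosettes) and
    multiple concentric shells (pearls).  Bins span [0, min(H, W)/2].
    Returns zeros when the image has no dark pixels.
    """
    img = np.asarray(img)
    ys, xs = np.nonzero(img <= dark_threshold)
    if ys.size == 0:
        return np.zeros(n_bins)
    cy, cx = ys.mean(), xs.mean()
    d = np.hypot(ys - cy, xs - cx)
    r_max = min(img.shape) / 2.0
    hist, _ = np.histogram(d, bins=n_bins, range=(0, r_max))
    total = hist.sum()
    return hist / total if total else np.zeros(n_bins)


def dataset_checksum(manifest: pd.DataFrame) -> str:
    """SHA-256 over all image files in manifest order (reproducibility)."""
    h = hashlib.sha256()
    for path in manifest["path"]:
        h.update(Path(path).read_bytes())
    return h.hexdigest()
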