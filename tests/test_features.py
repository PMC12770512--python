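"""Feature processing: pre-map, Otsu, cleanup, composition, lightening."""

from collections import deque

import numpy as np
import pytest

from lungcyto.errors import InputError
from lungcyto.features import (FeatureConfig, binarize_foreground,
                               compose_final, extract_features,
                               midtone_lighten, otsu_threshold, premap_dark,
                               quality_metrics, remove_small_components)


def brute_force_otsu(img: np.ndarray) -> int:
    """Independent double-loop scan over all 256 candidates."""
    v = img.ravel().astype(float)
    best_var, best_t = -1.0, 0
    for t in range(256):
        c0 = v[v <= t]
        c1 = v[v > t]
        if len(c0) == 0 or len(c1) == 0:
            var = 0.0
        else:
            w0 = len(c0) / len(v)
            var = w0 * (1 - w0) * (c0.mean() - c1.mean()) ** 2
        if var > best_var + 1e-12:
            best_var, best_t = var, t
    return best_t


def flood_fill_components(mask: np.ndarray, connectivity: int):
    """BFS labeling oracle; yields lists of pixel coordinates."""
    offsets = [(-1, 0), (1, 0), (0, -1), (0, 1)]
    if connectivity == 8:
        offsets += [(-1, -1), (-1, 1), (1, -1), (1, 1)]
    seen = np.zeros_like(mask, dtype=bool)
    h, w = mask.shape
    for sy in range(h):
        for sx in range(w):
            if not mask[sy, sx] or seen[sy, sx]:
                continue
            comp = []
            q = deque([(sy, sx)])
            seen[sy, sx] = True
            while q:
                y, x = q.popleft()
                comp.append((y, x))
                for dy, dx in offsets:
                    ny, nx = y + dy, x + dx
                    if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] \
                            and not seen[ny, nx]:
                        seen[ny, nx] = True
                        q.append((ny, nx))
            yield comp


def test_premap_boundary():
    img = np.array([[60, 61, 255]], dtype=np.uint8)
    out, flags = premap_dark(img)
    assert list(out[0]) == [0, 61, 255]
    assert list(flags[0]) == [True, False, False]


def test_premap_all_white_unchanged():
    img = np.full((5, 5), 255, dtype=np.uint8)
    out, flags = premap_dark(img)
    assert np.array_equal(out, img)
    assert not flags.any()


def test_otsu_two_mass_example():
    # 50 pixels at 10 and 50 at 200: the variance curve is flat-maximal
    # on [10, 199]; the smallest maximizer is 10.
    img = np.array([10] * 50 + [200] * 50, dtype=np.uint8).reshape(10, 10)
    res = otsu_threshold(img)
    assert res.threshold == 10
    assert res.between_class_variance_curve.shape == (256,)
    assert np.all(res.between_class_variance_curve >= 0)


def test_otsu_constant_image_convention():
    assert otsu_threshold(np.full((4, 4), 112, dtype=np.uint8)).threshold == 112


def test_otsu_empty_image_rejected():
    with pytest.raises(InputError):
        otsu_threshold(np.zeros((0, 0), dtype=np.uint8))


def test_otsu_matches_brute_force_oracle(rng):
    for _ in range(30):
        img = rng.integers(0, 256, (16, 16)).astype(np.uint8)
        assert otsu_threshold(img).threshold == brute_force_otsu(img)


def test_binarize_boundary_inclusion():
    img = np.array([[112, 240, 50]], dtype=np.uint8)
    mask = binarize_foreground(img, 112)
    assert list(mask[0]) == [True, False, True]
    assert binarize_foreground(img, 255).all()


def test_remove_small_components_size_boundary():
    cfg = FeatureConfig(min_object_px=30)
    mask = np.zeros((20, 20), dtype=bool)
    mask[1:6, 1:7] = True          # 30 px -> kept
    small = np.zeros((20, 20), dtype=bool)
    small[10:15, 10:16] = True
    small[14, 15] = False          # 29 px -> removed
    assert remove_small_components(mask, cfg).sum() == 30
    assert remove_small_components(small, cfg).sum() == 0
    empty = np.zeros((5, 5), dtype=bool)
    assert not remove_small_components(empty, cfg).any()


@pytest.mark.parametrize("connectivity", [4, 8])
def test_remove_small_components_matches_flood_fill(rng, connectivity):
    cfg = FeatureConfig(min_object_px=5, connectivity=connectivity)
    for _ in range(15):
        mask = rng.random((24, 24)) < 0.35
        expected = np.zeros_like(mask)
        for comp in flood_fill_components(mask, connectivity):
            if len(comp) >= cfg.min_object_px:
                for y, x in comp:
                    expected[y, x] = True
        assert np.array_equal(remove_small_components(mask, cfg), expected)


def test_remove_small_components_idempotent_never_adds(rng):
    cfg = FeatureConfig(min_object_px=8)
    mask = rng.random((32, 32)) < 0.4
    once = remove_small_components(mask, cfg)
    assert not (once & ~mask).any()
    assert np.array_equal(once, remove_small_components(once, cfg))


def test_compose_priority_rule():
    enhanced = np.array([[0, 180, 140]], dtype=np.uint8)
    dark = np.array([[True, False, False]])
    fg = np.array([[True, False, True]])
    out = compose_final(enhanced, fg, dark)
    assert list(out[0]) == [0, 255, 140]


def test_compose_exhaustive_three_way_partition(rng):
    enhanced = rng.integers(0, 256, (32, 32)).astype(np.uint8)
    fg = rng.random((32, 32)) < 0.5
    dark = rng.random((32, 32)) < 0.2
    out = compose_final(enhanced, fg, dark)
    # every pixel is exactly one of: black (dark), white (background),
    # or the enhanced value (foreground) -- checked exhaustively
    assert np.all(out[dark] == 0)
    assert np.all(out[~dark & ~fg] == 255)
    keep = ~dark & fg
    assert np.array_equal(out[keep], enhanced[keep])


def test_compose_shape_mismatch():
    with pytest.raises(InputError):
        compose_final(np.zeros((3, 3), dtype=np.uint8),
                      np.zeros((3, 4), dtype=bool),
                      np.zeros((3, 3), dtype=bool))


@pytest.mark.parametrize("v,expected", [(0, 0), (100, 130), (200, 255),
                                        (255, 255)])
def test_midtone_lighten_values(v, expected):
    img = np.array([[v]], dtype=np.uint8)
    assert midtone_lighten(img)[0, 0] == expected


def test_midtone_lighten_order_preserving():
    img = np.arange(256, dtype=np.uint8).reshape(16, 16)
    out = midtone_lighten(img).astype(int).ravel()
    assert np.all(np.diff(out[np.argsort(img.ravel())]) >= 0)


def test_quality_metrics_identity_and_guards():
    img = np.array([[30, 30, 200], [210, 220, 230]], dtype=np.uint8)
    fg = img <= 100
    dark = np.zeros_like(fg)
    qm = quality_metrics(img, img, fg, dark)
    assert qm["snr_relative_change"] == 0
    assert qm["midtone_contrast_relative_change"] is None  # no midtones
    const_bg = np.where(fg, img, 240).astype(np.uint8)
    qm2 = quality_metrics(const_bg, const_bg, fg, dark)
    assert qm2["snr_before"] is None  # zero-spread baseline is undefined


def test_extract_features_full_stage_deterministic(rng):
    img = rng.integers(0, 256, (48, 48)).astype(np.uint8)
    a = extract_features(img)
    b = extract_features(img)
    assert np.array_equal(a[0], b[0])
    assert a[3].threshold == b[3].threshold
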