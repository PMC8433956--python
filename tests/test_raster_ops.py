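"""Pixel operators checked against brute-force oracles and morphology identities."""

import numpy as np
import pytest

from woundarea import (box_blur, canny_edges, dilate, erode, invert,
                       otsu_threshold, structuring_element, to_grayscale)
from woundarea.errors import (ConfigError, DegenerateHistogramError,
                              InvalidImageError, InvalidMaskError)

EIGHT = np.ones((3, 3), dtype=bool)


# ---------------------------------------------------------------- grayscale

def _luma_oracle(rgb):
    return int(np.clip(np.floor(0.299 * rgb[0] + 0.587 * rgb[1] + 0.114 * rgb[2] + 0.5), 0, 255))


@pytest.mark.parametrize("rgb,expected", [
    ((255, 255, 255), 255),
    ((0, 0, 0), 0),
    ((255, 0, 0), 76),       # 0.299*255 = 76.245 rounds down
    ((0, 255, 0), 150),
    ((0, 0, 255), 29),
])
def test_grayscale_known_pixels(rgb, expected):
    img = np.full((2, 2, 3), rgb, dtype=np.uint8)
    out = to_grayscale(img)
    assert out.dtype == np.uint8
    assert (out == expected).all()
    assert expected == _luma_oracle(rgb)


def test_grayscale_matches_luma_formula_on_random_pixels(rng):
    img = rng.integers(0, 256, size=(13, 17, 3), dtype=np.uint8)
    out = to_grayscale(img)
    expected = np.array([[_luma_oracle(px) for px in row] for row in img])
    np.testing.assert_array_equal(out, expected)


def test_grayscale_passthrough_and_validation(rng):
    gray = rng.integers(0, 256, size=(5, 5), dtype=np.uint8)
    np.testing.assert_array_equal(to_grayscale(gray), gray)
    with pytest.raises(InvalidImageError):
        to_grayscale(gray.astype(np.float32))
    with pytest.raises(InvalidImageError):
        to_grayscale(np.zeros((4, 4, 4), dtype=np.uint8))


# ----------------------------------------------------------------- box blur

def _blur_oracle(img, k):
    pad = k // 2
    p = np.pad(img.astype(np.int64), pad, mode="reflect")
    h, w = img.shape
    out = np.empty_like(img)
    for i in range(h):
        for j in range(w):
            s = p[i:i + k, j:j + k].sum()
            out[i, j] = (2 * s + k * k) // (2 * k * k)
    return out


def test_box_blur_matches_sliding_window_oracle(rng):
    img = rng.integers(0, 256, size=(14, 11), dtype=np.uint8)
    for k in (3, 5, 9):
        np.testing.assert_array_equal(box_blur(img, k), _blur_oracle(img, k))


def test_box_blur_constant_and_identity():
    img = np.full((9, 9), 100, dtype=np.uint8)
    np.testing.assert_array_equal(box_blur(img, 5), img)
    varied = np.arange(81, dtype=np.uint8).reshape(9, 9)
    np.testing.assert_array_equal(box_blur(varied, 1), varied)


def test_box_blur_point_source():
    img = np.zeros((5, 5), dtype=np.uint8)
    img[2, 2] = 9
    out = box_blur(img, 3)
    expected = np.zeros((5, 5), dtype=np.uint8)
    expected[1:4, 1:4] = 1
    np.testing.assert_array_equal(out, expected)


def test_box_blur_range_contraction(rng):
    img = rng.integers(40, 200, size=(20, 20), dtype=np.uint8)
    out = box_blur(img, 7)
    assert out.min() >= img.min() and out.max() <= img.max()


def test_box_blur_rejects_bad_kernels():
    img = np.zeros((8, 8), dtype=np.uint8)
    for k in (0, -1, 2, 4):
        with pytest.raises(ConfigError):
            box_blur(img, k)
    with pytest.raises(ConfigError):
        box_blur(img, 9)      # larger than the image


# --------------------------------------------------------------------- otsu

def _otsu_oracle(img):
    """Exhaustive search of the between-class variance over all 256 thresholds."""
    hist = np.bincount(img.ravel(), minlength=256).astype(float)
    best_t, best_crit = None, -1.0
    for t in range(256):
        w0 = hist[:t + 1].sum()
        w1 = hist[t + 1:].sum()
        if w0 == 0 or w1 == 0:
            continue
        mu0 = (hist[:t + 1] * np.arange(t + 1)).sum() / w0
        mu1 = (hist[t + 1:] * np.arange(t + 1, 256)).sum() / w1
        crit = w0 * w1 * (mu0 - mu1) ** 2
        if crit > best_crit:
            best_crit, best_t = crit, t
    return best_t


def test_otsu_separates_bimodal_exactly():
    img = np.concatenate([np.full(50, 50), np.full(50, 200)]).astype(np.uint8).reshape(10, 10)
    t, mask = otsu_threshold(img)
    assert 50 <= t < 200
    assert ((mask == 255) == (img == 200)).all()


def test_otsu_single_bright_pixel():
    img = np.full((2, 2), 10, dtype=np.uint8)
    img[0, 0] = 240
    _, mask = otsu_threshold(img)
    assert (mask == 255).sum() == 1 and mask[0, 0] == 255


def test_otsu_equals_exhaustive_search(rng):
    for _ in range(60):
        img = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
        t, mask = otsu_threshold(img)
        assert t == _otsu_oracle(img)
        assert ((mask == 255) == (img > t)).all()


def test_otsu_constant_image_is_degenerate():
    with pytest.raises(DegenerateHistogramError):
        otsu_threshold(np.full((6, 6), 128, dtype=np.uint8))


# ------------------------------------------------------------------- invert

def test_invert_involution_and_examples(random_masks):
    zeros = np.zeros((4, 4), dtype=np.uint8)
    np.testing.assert_array_equal(invert(zeros), np.full((4, 4), 255, dtype=np.uint8))
    checker = (np.indices((6, 6)).sum(0) % 2 * 255).astype(np.uint8)
    np.testing.assert_array_equal(invert(checker), 255 - checker)
    for m in random_masks:
        np.testing.assert_array_equal(invert(invert(m)), m)
    with pytest.raises(InvalidMaskError):
        invert(np.full((3, 3), 7, dtype=np.uint8))


# --------------------------------------------------------------- morphology

def _dilate_oracle(mask, fp):
    h, w = mask.shape
    k = fp.shape[0]
    r = k // 2
    out = np.zeros_like(mask)
    for i in range(h):
        for j in range(w):
            if mask[i, j] != 255:
                continue
            for di in range(-r, r + 1):
                for dj in range(-r, r + 1):
                    if fp[di + r, dj + r] and 0 <= i + di < h and 0 <= j + dj < w:
                        out[i + di, j + dj] = 255
    return out


def test_elliptical_footprint_shape():
    se = structuring_element("ellipse", 11)
    fp = se.footprint
    assert fp.shape == (11, 11) and fp[5, 5]
    assert fp[5, 0] and fp[5, 10] and fp[0, 5] and fp[10, 5]   # axis extremes included
    assert not fp[0, 0] and not fp[10, 10]                     # corners excluded
    assert structuring_element("ellipse", 1).footprint.all()
    with pytest.raises(ConfigError):
        structuring_element("ellipse", 4)


def test_dilate_single_pixel_stamps_footprint():
    se = structuring_element("ellipse", 11)
    mask = np.zeros((25, 25), dtype=np.uint8)
    mask[12, 12] = 255
    out = dilate(mask, se)
    np.testing.assert_array_equal((out[7:18, 7:18] == 255), se.footprint)
    assert (out == 255).sum() == se.footprint.sum()


def test_dilate_bridges_nearby_pixels():
    from scipy import ndimage
    se = structuring_element("ellipse", 11)
    mask = np.zeros((30, 30), dtype=np.uint8)
    mask[15, 10] = mask[15, 18] = 255      # 8 apart
    out = dilate(mask, se)
    _, n = ndimage.label(out > 0, structure=EIGHT)
    assert n == 1


def test_dilate_matches_brute_force(random_masks):
    se = structuring_element("ellipse", 5)
    for m in random_masks[:3]:
        np.testing.assert_array_equal(dilate(m, se), _dilate_oracle(m, se.footprint))


def test_erode_all_white_leaves_border_band():
    se = structuring_element("rectangle", 5)
    mask = np.full((12, 12), 255, dtype=np.uint8)
    out = erode(mask, se)
    expected = np.zeros_like(mask)
    expected[2:-2, 2:-2] = 255
    np.testing.assert_array_equal(out, expected)


def test_erode_single_pixel_vanishes():
    se = structuring_element("ellipse", 11)
    mask = np.zeros((20, 20), dtype=np.uint8)
    mask[10, 10] = 255
    assert not erode(mask, se).any()


def test_morphology_identities(rng):
    """Extensivity, anti-extensivity, duality and closing idempotence.

    The identities are stated for foreground clear of the image border: with
    background padding, erosion eats any foreground the dilation pushed
    against the frame, so random content is embedded with a 6-px margin
    (> twice the SE radius) where the padding policy cannot interfere.
    """
    se = structuring_element("ellipse", 5)
    for p in (0.2, 0.4, 0.6, 0.8):
        m = np.zeros((28, 28), dtype=np.uint8)
        m[6:-6, 6:-6] = (rng.random((16, 16)) < p).astype(np.uint8) * 255
        d, e = dilate(m, se), erode(m, se)
        assert ((d == 255) | (m == 0)).all()             # dilation extensive
        assert ((e == 0) | (m == 255)).all()             # erosion anti-extensive
        np.testing.assert_array_equal(e, invert(dilate(invert(m), se)))   # duality
        closed = erode(dilate(m, se), se)
        assert ((closed == 255) | (m == 0)).all()        # closing extensive
        np.testing.assert_array_equal(closed, erode(dilate(closed, se), se))  # idempotent


def test_morphology_rejects_oversized_se():
    se = structuring_element("ellipse", 11)
    with pytest.raises(ConfigError):
        dilate(np.zeros((5, 5), dtype=np.uint8), se)


# -------------------------------------------------------------------- canny

def _boundary(mask):
    """Foreground pixels 8-adjacent to background or to the image border."""
    fg = mask > 0
    pad = np.pad(fg, 1, mode="constant")
    h, w = fg.shape
    out = np.zeros_like(fg)
    for i in range(h):
        for j in range(w):
            if fg[i, j] and not pad[i:i + 3, j:j + 3].all():
                out[i, j] = True
    return out


def _chebyshev_near(points_mask, target_mask, dist=1):
    from scipy import ndimage
    grown = ndimage.binary_dilation(target_mask, iterations=dist, structure=EIGHT)
    return (~points_mask | grown).all()


def test_canny_empty_mask_has_no_edges():
    assert not canny_edges(np.zeros((32, 32), dtype=np.uint8)).any()
    assert not canny_edges(np.full((32, 32), 255, dtype=np.uint8)).any()


def test_canny_square_edges_hug_the_boundary():
    mask = np.zeros((64, 64), dtype=np.uint8)
    mask[22:42, 22:42] = 255
    edges = canny_edges(mask)
    assert edges.any()
    assert _chebyshev_near(edges > 0, _boundary(mask))
    interior = np.zeros_like(mask, dtype=bool)
    interior[26:38, 26:38] = True
    assert not (edges[interior] > 0).any()


def test_canny_disk_gives_single_closed_ring():
    from scipy import ndimage
    yy, xx = np.mgrid[0:64, 0:64]
    mask = np.where((xx - 32) ** 2 + (yy - 32) ** 2 <= 15 ** 2, 255, 0).astype(np.uint8)
    edges = canny_edges(mask)
    _, n = ndimage.label(edges > 0, structure=EIGHT)
    assert n == 1
    assert _chebyshev_near(edges > 0, _boundary(mask))


def test_canny_threshold_insensitivity_on_binary_masks():
    """Any mid-range threshold pair finds the same boundary on a {0,255} mask."""
    mask = np.zeros((48, 48), dtype=np.uint8)
    mask[10:35, 14:40] = 255
    reference = canny_edges(mask, 100, 200)
    for low, high in [(50, 120), (80, 220), (120, 180)]:
        np.testing.assert_array_equal(canny_edges(mask, low, high), reference)


def test_canny_agrees_with_skimage_oracle():
    """Independent cross-check: both edge sets lie within 1 px of each other."""
    from skimage.feature import canny as sk_canny
    yy, xx = np.mgrid[0:60, 0:60]
    mask = np.where((xx - 30) ** 2 / 14 ** 2 + (yy - 30) ** 2 / 9 ** 2 <= 1, 255, 0).astype(np.uint8)
    ours = canny_edges(mask) > 0
    theirs = sk_canny(mask.astype(float) / 255.0, sigma=1.0)
    assert _chebyshev_near(ours, theirs) and _chebyshev_near(theirs, ours)


def test_canny_rejects_bad_thresholds():
    mask = np.zeros((8, 8), dtype=np.uint8)
    with pytest.raises(ConfigError):
        canny_edges(mask, 200, 100)
    with pytest.raises(ConfigError):
        canny_edges(mask, 0, 100)
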