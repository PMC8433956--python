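"""Pixel-level operators used by the segmentation pipeline.

All operators act on 8-bit rasters held as numpy arrays: grayscale images are
``(H, W)`` uint8, RGB images ``(H, W, 3)`` uint8, and binary masks ``(H, W)``
uint8 restricted to the values {0, 255}.  Everything here is deterministic —
identical input bytes produce identical output bytes — which is what makes the
end-to-end measurement reproducible.

Conventions fixed by this module (the defaults the rest of the package
assumes):

* grayscale conversion uses the ITU-R BT.601 luma weights 0.299/0.587/0.114;
* box blur pads by reflection and rounds half away from zero, implemented
  with an exact integer summed-area table so no platform-dependent floating
  rounding can flip a pixel;
* morphology pads with background (0) at the image border;
* the elliptical structuring element contains every cell of the k x k box
  whose centre lies inside or on the axis-aligned ellipse with semi-axes
  (k-1)/2.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .errors import (
    ConfigError,
    DegenerateHistogramError,
    InvalidImageError,
    InvalidMaskError,
)

__all__ = [
    "StructuringElement",
    "structuring_element",
    "to_grayscale",
    "box_blur",
    "otsu_threshold",
    "invert",
    "dilate",
    "erode",
    "canny_edges",
]

# BT.601 luma weights; the conventional RGB -> gray mapping.
_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def _as_gray(img: np.ndarray, op: str) -> np.ndarray:
    img = np.asarray(img)
    if img.dtype != np.uint8 or img.ndim != 2 or img.size == 0:
        raise InvalidImageError(f"{op} expects a non-empty 8-bit grayscale image, "
                                f"got dtype={img.dtype}, shape={img.shape}")
    return img


def _as_mask(mask: np.ndarray, op: str) -> np.ndarray:
    mask = np.asarray(mask)
    if mask.dtype != np.uint8 or mask.ndim != 2 or mask.size == 0:
        raise InvalidMaskError(f"{op} expects a non-empty 8-bit 2-D mask, "
                               f"got dtype={mask.dtype}, shape={mask.shape}")
    if not np.isin(mask, (0, 255)).all():
        raise InvalidMaskError(f"{op}: mask contains values other than 0 and 255")
    return mask


@dataclass(frozen=True)
class StructuringElement:
    """A morphological neighbourhood footprint on a k x k grid.

    Attributes
    ----------
    shape : {"ellipse", "rectangle"}
    size : odd side length k of the bounding box
    footprint : boolean (k, k) array; the origin (centre cell) is always a member
    """

    shape: str
    size: int
    footprint: np.ndarray

    def __post_init__(self) -> None:
        k = self.size
        if k < 1 or k % 2 == 0:
            raise ConfigError(f"structuring element size must be odd and >= 1, got {k}")
        fp = np.asarray(self.footprint, dtype=bool)
        if fp.shape != (k, k):
            raise ConfigError("footprint shape does not match size")
        if not fp[k // 2, k // 2]:
            raise ConfigError("structuring element must contain its origin")
        object.__setattr__(self, "footprint", fp)


def structuring_element(shape: str = "ellipse", size: int = 11) -> StructuringElement:
    """Build an elliptical or rectangular structuring element.

    The elliptical footprint is the discretised ellipse inscribed in the
    k x k box: cell (i, j) belongs iff its centre satisfies
    ``(di/a)^2 + (dj/a)^2 <= 1`` with ``a = (k-1)/2`` (inclusive boundary, so
    the four axis extremes are members).  ``size=1`` degenerates to the
    single origin cell for either shape.
    """
    if size < 1 or size % 2 == 0:
        raise ConfigError(f"structuring element size must be odd and >= 1, got {size}")
    if shape == "rectangle":
        fp = np.ones((size, size), dtype=bool)
    elif shape == "ellipse":
        a = (size - 1) / 2.0
        ii, jj = np.mgrid[0:size, 0:size]
        if a == 0:
            fp = np.ones((1, 1), dtype=bool)
        else:
            fp = ((ii - a) / a) ** 2 + ((jj - a) / a) ** 2 <= 1.0 + 1e-12
    else:
        raise ConfigError(f"unknown structuring element shape {shape!r}")
    return StructuringElement(shape=shape, size=size, footprint=fp)


def to_grayscale(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image to 8-bit grayscale; grayscale input passes through.

    Per pixel the luma 0.299 R + 0.587 G + 0.114 B is rounded half away from
    zero and clipped to [0, 255].
    """
    img = np.asarray(img)
    if img.dtype != np.uint8 or img.size == 0:
        raise InvalidImageError(f"to_grayscale expects 8-bit input, got dtype={img.dtype}")
    if img.ndim == 2:
        return img.copy()
    if img.ndim != 3 or img.shape[2] != 3:
        raise InvalidImageError(f"to_grayscale expects (H, W) or (H, W, 3), got {img.shape}")
    luma = img.astype(np.float64) @ _LUMA_WEIGHTS
    return np.clip(np.floor(luma + 0.5), 0, 255).astype(np.uint8)


def box_blur(img: np.ndarray, k: int = 19) -> np.ndarray:
    """Mean filter with a k x k window, reflect padding, integer rounding.

    Each output pixel is the mean of the k x k window centred on it, with the
    image reflected at its borders and the mean rounded half away from zero.
    The window sums are accumulated in an int64 summed-area table, so results
    are exact and bit-stable.
    """
    img = _as_gray(img, "box_blur")
    if k < 1 or k % 2 == 0:
        raise ConfigError(f"box_blur kernel must be odd and >= 1, got {k}")
    h, w = img.shape
    if k > min(h, w):
        raise ConfigError(f"box_blur kernel {k} exceeds image size {h}x{w}")
    if k == 1:
        return img.copy()
    pad = k // 2
    padded = np.pad(img.astype(np.int64), pad, mode="reflect")
    sat = np.zeros((padded.shape[0] + 1, padded.shape[1] + 1), dtype=np.int64)
    np.cumsum(np.cumsum(padded, axis=0), axis=1, out=sat[1:, 1:])
    sums = sat[k:, k:] - sat[:-k, k:] - sat[k:, :-k] + sat[:-k, :-k]
    # floor((s + k^2/2) / k^2) == round-half-up for non-negative s
    out = (2 * sums + k * k) // (2 * k * k)
    return out.astype(np.uint8)


def otsu_threshold(img: np.ndarray) -> tuple[int, np.ndarray]:
    """Otsu's histogram threshold plus the resulting binary mask.

    Returns ``(t, mask)`` where ``t`` maximises the between-class variance
    ``w0(t) * w1(t) * (mu0(t) - mu1(t))^2`` over the 256-bin histogram, with
    class 0 the intensities ``<= t``.  Ties take the smallest ``t``.  The mask
    is 255 where ``intensity > t`` — bright pixels white — so for a dark wound
    on lighter skin the wound is black until :func:`invert` is applied.

    Raises
    ------
    DegenerateHistogramError
        if the image is constant (no split produces two classes).
    """
    img = _as_gray(img, "otsu_threshold")
    hist = np.bincount(img.ravel(), minlength=256).astype(np.float64)
    if np.count_nonzero(hist) < 2:
        raise DegenerateHistogramError(
            "constant image: Otsu's criterion is undefined on a single-valued histogram")
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)                     # pixels with intensity <= t
    m0 = np.cumsum(hist * levels)            # their intensity sum
    total, grand = w0[-1], m0[-1]
    w1 = total - w0
    valid = (w0 > 0) & (w1 > 0)              # both classes non-empty
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = m0 / w0
        mu1 = (grand - m0) / w1
    crit = np.where(valid, w0 * w1 * (mu0 - mu1) ** 2, -np.inf)
    t = int(np.argmax(crit))                 # argmax returns the first (smallest) maximiser
    mask = np.where(img > t, 255, 0).astype(np.uint8)
    return t, mask


def invert(mask: np.ndarray) -> np.ndarray:
    """Swap foreground and background: 0 <-> 255."""
    mask = _as_mask(mask, "invert")
    return (255 - mask).astype(np.uint8)


def _check_se_fits(mask: np.ndarray, se: StructuringElement, op: str) -> None:
    if se.size > min(mask.shape):
        raise ConfigError(f"{op}: structuring element {se.size} exceeds image size {mask.shape}")


def dilate(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary dilation: a pixel is foreground iff any footprint neighbour is.

    The border is treated as background.  Because the origin belongs to the
    footprint, dilation is extensive (output contains the input).
    """
    mask = _as_mask(mask, "dilate")
    _check_se_fits(mask, se, "dilate")
    out = ndimage.binary_dilation(mask > 0, structure=se.footprint, border_value=0)
    return np.where(out, 255, 0).astype(np.uint8)


def erode(mask: np.ndarray, se: StructuringElement) -> np.ndarray:
    """Binary erosion: a pixel stays foreground iff all footprint neighbours are.

    The border is background, so an all-white mask erodes to white with a
    black band where the footprint exits the image.  For symmetric footprints
    erosion is the inversion-dual of dilation.
    """
    mask = _as_mask(mask, "erode")
    _check_se_fits(mask, se, "erode")
    out = ndimage.binary_erosion(mask > 0, structure=se.footprint, border_value=0)
    return np.where(out, 255, 0).astype(np.uint8)


def canny_edges(mask: np.ndarray, low: int = 100, high: int = 200) -> np.ndarray:
    """Canny edge detection specialised to this pipeline's binary-mask input.

    Full Canny machinery — Gaussian smoothing (sigma 1), Sobel gradients,
    non-maximum suppression along the quantised gradient direction, and
    double-threshold hysteresis — applied to the {0, 255} mask.  The gradient
    magnitude is rescaled so its maximum maps to 255 before thresholding,
    which makes any mid-range (low, high) pair detect the same boundary on a
    binary input: the only gradient ridge is the foreground/background edge.

    Returns a thin (<= 2 px) edge mask lying on the boundary between
    foreground and background.
    """
    mask = _as_mask(mask, "canny_edges")
    if not (0 < low < high < 256):
        raise ConfigError(f"canny thresholds must satisfy 0 < low < high < 256, got {low}, {high}")
    f = ndimage.gaussian_filter(mask.astype(np.float64), sigma=1.0, mode="nearest")
    gx = ndimage.sobel(f, axis=1, mode="nearest")
    gy = ndimage.sobel(f, axis=0, mode="nearest")
    mag = np.hypot(gx, gy)
    peak = mag.max()
    if peak == 0:
        return np.zeros_like(mask)
    mag *= 255.0 / peak

    # Non-maximum suppression: keep pixels that are local maxima along the
    # gradient direction, quantised to the four principal orientations.
    angle = np.mod(np.degrees(np.arctan2(gy, gx)), 180.0)
    padded = np.pad(mag, 1, mode="constant")
    c = padded[1:-1, 1:-1]
    east, west = padded[1:-1, 2:], padded[1:-1, :-2]
    south, north = padded[2:, 1:-1], padded[:-2, 1:-1]
    se_, nw = padded[2:, 2:], padded[:-2, :-2]
    sw, ne = padded[2:, :-2], padded[:-2, 2:]
    horiz = (angle < 22.5) | (angle >= 157.5)          # gradient ~ horizontal
    diag1 = (angle >= 22.5) & (angle < 67.5)           # gradient ~ down-right
    vert = (angle >= 67.5) & (angle < 112.5)           # gradient ~ vertical
    n1 = np.select([horiz, diag1, vert], [east, se_, south], default=sw)
    n2 = np.select([horiz, diag1, vert], [west, nw, north], default=ne)
    ridge = (c >= n1) & (c >= n2) & (c > 0)

    strong = ridge & (mag >= high)
    weak = ridge & (mag >= low)
    if not strong.any():
        return np.zeros_like(mask)
    # Hysteresis: keep weak components that contain at least one strong pixel.
    labels, n = ndimage.label(weak, structure=np.ones((3, 3), dtype=bool))
    keep = np.zeros(n + 1, dtype=bool)
    keep[np.unique(labels[strong])] = True
    keep[0] = False
    return np.where(keep[labels], 255, 0).astype(np.uint8)
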