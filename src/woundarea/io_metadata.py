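"""Image decoding and physical-resolution (DPI) metadata handling.

The pixel-to-centimetre conversion is only as good as the image's declared
dots-per-inch, so DPI handling is strict here: a file without resolution
metadata raises :class:`~woundarea.errors.MissingDPIError` unless the caller
supplies an explicit override.  Silently defaulting to 72 or 96 DPI — what
many viewers do — would scale every reported area by an invisible factor.

Formats and where their DPI lives:

* PNG — the ``pHYs`` chunk, integer pixels per metre (converted by
  ``px/m * 0.0254``; 300 DPI is not exactly representable, hence the 0.1%
  tolerance used wherever DPI round-trips are compared);
* JPEG — JFIF density field (dots/inch, or dots/cm scaled by 2.54) or EXIF
  resolution tags;
* TIFF — tags 282/283/296.

Pillow abstracts all three behind its ``dpi`` info key, which this module
relies on.  Read DPI values are reported to four significant figures so a
pHYs round-trip of 300 DPI (11811 px/m = 299.9994 DPI) reads back as 300.0.
EXIF orientation is ignored: pixels are used as stored.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image, UnidentifiedImageError

from .errors import DecodeError, FormatError, InvalidImageError, MissingDPIError

__all__ = ["ImageMetadata", "read_image", "write_image"]

_SUPPORTED = {".png": "PNG", ".jpg": "JPEG", ".jpeg": "JPEG", ".tif": "TIFF", ".tiff": "TIFF"}


@dataclass(frozen=True)
class ImageMetadata:
    """Pixel dimensions and physical resolution of an image."""

    width_px: int
    height_px: int
    dpi_x: float
    dpi_y: float

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise InvalidImageError("image dimensions must be >= 1 pixel")
        if not (self.dpi_x > 0 and self.dpi_y > 0):
            raise InvalidImageError(f"DPI must be positive, got ({self.dpi_x}, {self.dpi_y})")

    def to_dict(self) -> dict:
        return {"width_px": self.width_px, "height_px": self.height_px,
                "dpi_x": self.dpi_x, "dpi_y": self.dpi_y}


def _round_sig(x: float, sig: int = 4) -> float:
    if x == 0:
        return 0.0
    return round(x, sig - 1 - math.floor(math.log10(abs(x))))


def read_image(path: str | Path, dpi_override: float | None = None) -> tuple[np.ndarray, ImageMetadata]:
    """Decode a PNG/JPEG/TIFF file into pixels plus metadata.

    Returns ``(pixels, meta)`` where pixels are uint8, shape ``(H, W)`` for
    grayscale or ``(H, W, 3)`` for colour (palette/alpha images are flattened
    to RGB).  ``dpi_override`` substitutes for absent resolution metadata and,
    when given, always wins over the file's own values.

    Raises
    ------
    DecodeError
        if the file does not exist or cannot be decoded.
    MissingDPIError
        if the file carries no resolution metadata and no override is given.
    """
    path = Path(path)
    try:
        with Image.open(path) as im:
            im.load()
            dpi = im.info.get("dpi")
            if im.mode == "L":
                pixels = np.asarray(im, dtype=np.uint8)
            elif im.mode == "RGB":
                pixels = np.asarray(im, dtype=np.uint8)
            else:
                pixels = np.asarray(im.convert("RGB"), dtype=np.uint8)
    except FileNotFoundError as exc:
        raise DecodeError(f"no such file: {path}") from exc
    except (UnidentifiedImageError, OSError) as exc:
        raise DecodeError(f"cannot decode {path}: {exc}") from exc

    if dpi_override is not None:
        if dpi_override <= 0:
            raise InvalidImageError(f"dpi_override must be positive, got {dpi_override}")
        dpi_x = dpi_y = float(dpi_override)
    else:
        if dpi is None or not all(d and d > 0 for d in dpi[:2]):
            raise MissingDPIError(
                f"{path} carries no physical-resolution metadata; pass an explicit DPI override")
        dpi_x, dpi_y = _round_sig(float(dpi[0])), _round_sig(float(dpi[1]))

    h, w = pixels.shape[:2]
    return pixels, ImageMetadata(width_px=w, height_px=h, dpi_x=dpi_x, dpi_y=dpi_y)


def write_image(path: str | Path, img: np.ndarray, meta: ImageMetadata,
                jpeg_quality: int = 95) -> Path:
    """Encode pixels to PNG/TIFF/JPEG with DPI metadata embedded.

    PNG and TIFF round-trip pixels exactly; JPEG is lossy in pixels but its
    density metadata still round-trips.  DPI read back from PNG agrees within
    0.1% (pHYs stores integer pixels per metre).
    """
    path = Path(path)
    fmt = _SUPPORTED.get(path.suffix.lower())
    if fmt is None:
        raise FormatError(f"unsupported image extension {path.suffix!r} "
                          f"(use one of {sorted(_SUPPORTED)})")
    img = np.asarray(img)
    if img.dtype != np.uint8 or img.ndim not in (2, 3):
        raise InvalidImageError("write_image expects uint8 (H, W) or (H, W, 3) pixels")
    if img.shape[:2] != (meta.height_px, meta.width_px):
        raise InvalidImageError(f"pixel grid {img.shape[:2]} does not match metadata "
                                f"({meta.height_px}, {meta.width_px})")
    im = Image.fromarray(img)
    kwargs: dict = {"dpi": (meta.dpi_x, meta.dpi_y)}
    if fmt == "JPEG":
        kwargs["quality"] = jpeg_quality
    im.save(path, format=fmt, **kwargs)
    return path
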