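"""Pixel-to-metric conversion and the wound-area arithmetic.

The conversion rests on one identity: at D dots per inch, a length of p
pixels spans ``p * 2.54 / D`` centimetres.  The wound area in cm^2 is then
obtained by proportion rather than by squaring the per-pixel length — the
wound's share of the image's pixel area is applied to the image's area in
cm^2:

    width_cm  = round2(width_px  * 2.54 / dpi_x)
    height_cm = round2(height_px * 2.54 / dpi_y)
    total_cm2 = width_cm * height_cm
    wound_cm2 = round4(wound_px / total_px * total_cm2)

The rounding order matters and is part of the contract: width and height are
rounded to two decimals *before* being multiplied, and all rounding is half
away from zero.  For a 1062 x 706 px image at 300 DPI this yields
8.99 x 5.98 = 53.7602 cm^2, and a wound of 54,746.5 px^2 converts to
3.9254 cm^2.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from decimal import ROUND_HALF_UP, Decimal

from .errors import DomainError

__all__ = ["WoundMeasurement", "px_to_cm", "measure_wound", "round_half_up"]

CM_PER_INCH = 2.54


def round_half_up(x: float, ndigits: int) -> float:
    """Decimal rounding, ties away from zero (so 2.675 -> 2.68, -2.675 -> -2.68)."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def px_to_cm(value_px: float, dpi: float) -> float:
    """Convert a pixel length to centimetres at the given resolution, unrounded."""
    if dpi <= 0:
        raise DomainError(f"dpi must be positive, got {dpi}")
    if value_px < 0:
        raise DomainError(f"pixel value must be non-negative, got {value_px}")
    return value_px * CM_PER_INCH / dpi


@dataclass(frozen=True)
class WoundMeasurement:
    """A wound's area in pixels and cm^2 together with the frame that scaled it.

    ``total_area_px`` is the full image's pixel area; ``wound_area_cm2`` is the
    wound's proportional share of ``total_area_cm2`` rounded to 4 decimals.
    """

    wound_area_px: float
    total_area_px: float
    width_px: float
    height_px: float
    width_cm: float
    height_cm: float
    total_area_cm2: float
    wound_area_cm2: float
    dpi_x: float
    dpi_y: float

    def __post_init__(self) -> None:
        if not 0 <= self.wound_area_px <= self.total_area_px:
            raise DomainError(f"wound area {self.wound_area_px} px^2 outside "
                              f"[0, {self.total_area_px}]")

    @property
    def wound_fraction(self) -> float:
        return self.wound_area_px / self.total_area_px

    def to_dict(self) -> dict:
        return asdict(self)

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def csv_row(self) -> dict:
        """Flat row for batch CSV output; area reported at 2 decimals."""
        d = self.to_dict()
        d["wound_area_cm2_2dp"] = round_half_up(self.wound_area_cm2, 2)
        return d


def measure_wound(wound_area_px: float, total_area_px: float, height_px: float,
                  dpi_x: float, dpi_y: float,
                  width_px: float | None = None) -> WoundMeasurement:
    """Convert a wound's pixel area to cm^2 given the image frame and DPI.

    ``width_px`` defaults to ``total_area_px / height_px``, i.e. the width
    consistent with the stated total pixel area; pass it explicitly when the
    true frame width is known.

    Raises
    ------
    DomainError
        for non-positive frame or DPI, or a wound larger than the frame.
    """
    if total_area_px <= 0:
        raise DomainError(f"total_area_px must be positive, got {total_area_px}")
    if height_px <= 0:
        raise DomainError(f"height_px must be positive, got {height_px}")
    if not 0 <= wound_area_px <= total_area_px:
        raise DomainError(f"wound_area_px {wound_area_px} outside [0, {total_area_px}]")
    if width_px is None:
        width_px = total_area_px / height_px
    elif width_px <= 0:
        raise DomainError(f"width_px must be positive, got {width_px}")

    width_cm = round_half_up(px_to_cm(width_px, dpi_x), 2)
    height_cm = round_half_up(px_to_cm(height_px, dpi_y), 2)
    total_cm2 = width_cm * height_cm
    wound_cm2 = round_half_up(wound_area_px / total_area_px * total_cm2, 4)
    return WoundMeasurement(
        wound_area_px=float(wound_area_px), total_area_px=float(total_area_px),
        width_px=float(width_px), height_px=float(height_px),
        width_cm=width_cm, height_cm=height_cm,
        total_area_cm2=total_cm2, wound_area_cm2=wound_cm2,
        dpi_x=float(dpi_x), dpi_y=float(dpi_y))
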