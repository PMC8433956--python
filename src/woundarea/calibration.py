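"""Cross-device comparison and MAE-based adjustment of area measurements.

The same photograph measured on two platforms (a desktop reference and a
mobile implementation of the identical pipeline) can yield different areas —
decoder differences, metadata handling and downscaling all bias the mobile
figure low.  This module quantifies that bias and corrects for it:

* per image, the difference ``test - ref`` in cm^2 and in percent of the
  reference;
* the mean absolute error (MAE) as the arithmetic mean of the absolute
  per-image percent differences;
* a multiplicative adjustment ``adjusted = test * (1 + MAE/100)`` applied to
  every test value, after which the differences are recomputed against the
  same references.

Differences are rounded to 2 decimals (cm^2) and 1 decimal (percent), half
away from zero, and the MAE is the mean of the rounded percent column — the
numbers a reader would recompute from the printed comparison table.

A ten-image reference dataset of paired desktop/mobile areas ships with the
package (:func:`load_reference_pairs`).
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable

from .errors import DomainError
from .units import round_half_up

__all__ = [
    "MeasurementPair",
    "ComparisonRow",
    "CalibrationReport",
    "compare",
    "adjust",
    "read_pairs_csv",
    "load_reference_pairs",
]


@dataclass(frozen=True)
class MeasurementPair:
    """One image's area measured on the reference and test platforms, in cm^2."""

    label: str
    ref_cm2: float
    test_cm2: float

    def __post_init__(self) -> None:
        if self.ref_cm2 <= 0:
            raise DomainError(f"{self.label}: reference area must be positive, got {self.ref_cm2}")
        if self.test_cm2 < 0:
            raise DomainError(f"{self.label}: test area must be non-negative, got {self.test_cm2}")


@dataclass(frozen=True)
class ComparisonRow:
    """Per-image difference of a (possibly adjusted) test value against its reference."""

    label: str
    ref_cm2: float
    test_cm2: float
    diff_cm2: float
    diff_pct: float


def _row(label: str, ref: float, test: float) -> ComparisonRow:
    return ComparisonRow(
        label=label, ref_cm2=ref, test_cm2=test,
        diff_cm2=round_half_up(test - ref, 2),
        diff_pct=round_half_up((test - ref) / ref * 100.0, 1))


@dataclass(frozen=True)
class CalibrationReport:
    """Comparison rows plus the MAE they imply."""

    rows: tuple[ComparisonRow, ...]

    @property
    def mae_pct(self) -> float:
        """Mean absolute percent difference over all rows (unrounded).

        ``math.fsum`` keeps the mean exactly permutation-invariant.
        """
        return math.fsum(abs(r.diff_pct) for r in self.rows) / len(self.rows)

    @property
    def mae_fraction(self) -> float:
        return self.mae_pct / 100.0

    def to_dicts(self) -> list[dict]:
        return [vars(r).copy() for r in self.rows]


def compare(pairs: Iterable[MeasurementPair]) -> CalibrationReport:
    """Per-image differences and MAE between two measurement series.

    Row order does not affect the MAE.  Raises ``DomainError`` on an empty
    input or a non-positive reference.
    """
    pairs = list(pairs)
    if not pairs:
        raise DomainError("compare needs at least one measurement pair")
    return CalibrationReport(rows=tuple(_row(p.label, p.ref_cm2, p.test_cm2) for p in pairs))


def adjust(pairs: Iterable[MeasurementPair], mae_fraction: float) -> CalibrationReport:
    """Scale every test value by ``(1 + mae_fraction)`` and re-compare.

    The adjusted value is rounded to 2 decimals before differencing, so the
    report shows exactly the numbers a table of adjusted areas would print.
    ``mae_fraction = 0`` is the identity on test values.
    """
    if mae_fraction < 0:
        raise DomainError(f"mae_fraction must be >= 0, got {mae_fraction}")
    pairs = list(pairs)
    if not pairs:
        raise DomainError("adjust needs at least one measurement pair")
    rows = []
    for p in pairs:
        adjusted = round_half_up(p.test_cm2 * (1.0 + mae_fraction), 2)
        rows.append(_row(p.label, p.ref_cm2, adjusted))
    return CalibrationReport(rows=tuple(rows))


def read_pairs_csv(path: str | Path) -> list[MeasurementPair]:
    """Read (label, ref_cm2, test_cm2) rows from a headered CSV file."""
    path = Path(path)
    pairs = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        required = {"label", "ref_cm2", "test_cm2"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise DomainError(f"{path}: expected CSV header with columns {sorted(required)}")
        for i, rec in enumerate(reader, start=2):
            try:
                pairs.append(MeasurementPair(label=rec["label"],
                                             ref_cm2=float(rec["ref_cm2"]),
                                             test_cm2=float(rec["test_cm2"])))
            except (TypeError, ValueError) as exc:
                raise DomainError(f"{path}: malformed row at line {i}: {exc}") from exc
    if not pairs:
        raise DomainError(f"{path}: no data rows")
    return pairs


def load_reference_pairs() -> list[MeasurementPair]:
    """The packaged ten-image desktop/mobile comparison dataset."""
    ref = resources.files("woundarea.data") / "platform_areas.csv"
    with resources.as_file(ref) as path:
        return read_pairs_csv(path)
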