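"""Contour extraction and the two contour-filtering rules of the pipeline.

Contours are traced by border following over pixel centres, the convention of
the classic connected-component boundary tracers: the contour of a filled
n x n square is the square through its boundary pixel centres, whose shoelace
area is (n-1)^2 — slightly below the pixel count n^2.  Areas here are polygon
(shoelace) areas in px^2, not pixel counts; the final wound figure this method
reports can be a half-integer precisely because it comes from the shoelace
formula.

Foreground regions are 8-connected, background 4-connected.  Hole boundaries
are traced as well (the contour list carries no hierarchy), and hole areas
participate in the mean-area filter and the total, mirroring the
retrieve-all-contours mode of the original procedure.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .errors import InvalidMaskError
from .raster_ops import _as_mask

__all__ = [
    "Contour",
    "ContourSet",
    "shoelace_area",
    "find_contours",
    "contour_area",
    "remove_small_shapes",
    "filter_by_mean_area",
    "total_area",
]

_EIGHT = np.ones((3, 3), dtype=bool)
_FOUR = ndimage.generate_binary_structure(2, 1)

# Clockwise Moore neighbourhood with x rightward, y downward:
# E, SE, S, SW, W, NW, N, NE as (dx, dy).
_DIRS = ((1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1), (0, -1), (1, -1))


def shoelace_area(points: np.ndarray) -> float:
    """Absolute polygon area of an ordered closed vertex list (last edge implicit)."""
    pts = np.asarray(points, dtype=np.float64)
    if pts.ndim != 2 or pts.shape[0] < 3:
        return 0.0
    x, y = pts[:, 0], pts[:, 1]
    return float(abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y)) / 2.0)


@dataclass(frozen=True)
class Contour:
    """A closed boundary polygon of (x, y) pixel coordinates, 0-based, y down."""

    points: np.ndarray
    is_hole: bool = False
    area_px: float = field(init=False)

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=np.int64)
        if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 1:
            raise InvalidMaskError("a contour needs an (N, 2) point array with N >= 1")
        object.__setattr__(self, "points", pts)
        object.__setattr__(self, "area_px", shoelace_area(pts))

    def __len__(self) -> int:
        return len(self.points)


@dataclass(frozen=True)
class ContourSet:
    """All boundary polygons of a mask — outer boundaries and holes, no hierarchy."""

    contours: tuple[Contour, ...]

    def __len__(self) -> int:
        return len(self.contours)

    def __iter__(self):
        return iter(self.contours)

    def __getitem__(self, i):
        return self.contours[i]

    @property
    def areas(self) -> np.ndarray:
        return np.array([c.area_px for c in self.contours], dtype=np.float64)

    def to_json(self) -> list:
        """Contours as plain lists of [x, y] pairs, for overlay/debug export."""
        return [{"is_hole": c.is_hole, "area_px": c.area_px,
                 "points": c.points.tolist()} for c in self.contours]


def _trace_boundary(region: np.ndarray, start: tuple[int, int]) -> np.ndarray:
    """Border following around one connected region, clockwise.

    ``region`` is a boolean array padded so the boundary never leaves it;
    ``start`` is the (x, y) of the region's topmost-leftmost pixel in padded
    coordinates.  From each boundary pixel the eight neighbours are scanned
    clockwise starting just after the direction pointing back at the previous
    pixel; the trace stops on re-leaving the start pixel by the same first
    move (Jacob's criterion), which closes the loop exactly once.
    """
    x0, y0 = start
    pts = [(x0, y0)]
    cx, cy = x0, y0
    prev_dir = 4          # W: the start pixel's west neighbour is background
    first_move = None
    while True:
        for step in range(1, 9):
            d = (prev_dir + step) % 8
            dx, dy = _DIRS[d]
            nx, ny = cx + dx, cy + dy
            if region[ny, nx]:
                break
        else:
            return np.array(pts, dtype=np.int64)       # isolated pixel
        if (cx, cy) == (x0, y0):
            if first_move is None:
                first_move = d
            elif d == first_move:
                break
        cx, cy = nx, ny
        pts.append((cx, cy))
        prev_dir = (d + 4) % 8
        if len(pts) > 8 * region.size:                 # safety net
            raise RuntimeError("boundary tracing failed to terminate")
    if len(pts) > 1 and pts[-1] == (x0, y0):
        pts.pop()                                      # drop duplicate closing vertex
    return np.array(pts, dtype=np.int64)


def _region_contours(labels: np.ndarray, n: int, is_hole: bool) -> list[tuple[tuple[int, int], Contour]]:
    """Outer boundary of every labelled region, keyed by its discovery pixel."""
    out: list[tuple[tuple[int, int], Contour]] = []
    slices = ndimage.find_objects(labels)
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        if sl is None:
            continue
        box = labels[sl] == lab
        ys, xs = np.nonzero(box)
        order = np.lexsort((xs, ys))
        ly, lx = int(ys[order[0]]), int(xs[order[0]])
        padded = np.pad(box, 1, mode="constant")
        loop = _trace_boundary(padded, (lx + 1, ly + 1))
        loop = loop - 1 + np.array([sl[1].start, sl[0].start])   # unpad, offset to image coords
        out.append(((ly + sl[0].start, lx + sl[1].start), Contour(points=loop, is_hole=is_hole)))
    return out


def find_contours(mask: np.ndarray) -> ContourSet:
    """Boundary polygons of all 8-connected foreground regions and their holes.

    Holes are 4-connected background regions that do not touch the image
    border; their own boundary is traced the same way.  The result is ordered
    by raster-scan position of each boundary's topmost-leftmost pixel, so the
    listing is deterministic.  An empty foreground yields an empty set.
    """
    mask = _as_mask(mask, "find_contours")
    fg = mask > 0
    if not fg.any():
        return ContourSet(contours=())
    labels, n = ndimage.label(fg, structure=_EIGHT)
    entries = _region_contours(labels, n, is_hole=False)

    bg_labels, bn = ndimage.label(~fg, structure=_FOUR)
    if bn:
        border = np.zeros_like(fg)
        border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
        touching = np.unique(bg_labels[border & ~fg])
        is_hole_label = np.ones(bn + 1, dtype=bool)
        is_hole_label[0] = False
        is_hole_label[touching] = False
        hole_mask = is_hole_label[bg_labels]
        if hole_mask.any():
            hole_labels, hn = ndimage.label(hole_mask, structure=_FOUR)
            entries.extend(_region_contours(hole_labels, hn, is_hole=True))

    entries.sort(key=lambda e: e[0])
    return ContourSet(contours=tuple(c for _, c in entries))


def contour_area(c: Contour) -> float:
    """Shoelace area of a contour in px^2 (0 for degenerate polygons)."""
    return c.area_px


def remove_small_shapes(mask: np.ndarray, min_area: float = 50) -> np.ndarray:
    """Erase foreground regions whose boundary-contour area is below ``min_area``.

    The threshold is strict: a region of contour area exactly ``min_area``
    survives.  Removed regions are painted background over their full pixel
    extent (not just their boundary).  Idempotent; output foreground is a
    subset of the input foreground.
    """
    mask = _as_mask(mask, "remove_small_shapes")
    if min_area < 0:
        raise InvalidMaskError(f"min_area must be >= 0, got {min_area}")
    fg = mask > 0
    if not fg.any() or min_area == 0:
        return mask.copy()
    labels, n = ndimage.label(fg, structure=_EIGHT)
    small = np.zeros(n + 1, dtype=bool)
    for (y0, x0), contour in _region_contours(labels, n, is_hole=False):
        if contour.area_px < min_area:
            small[labels[y0, x0]] = True
    out = mask.copy()
    out[small[labels]] = 0
    return out


def filter_by_mean_area(cs: ContourSet) -> ContourSet:
    """Keep only contours at least as large as the set's mean area.

    The maximum always survives, so a non-empty input yields a non-empty
    output; an empty set passes through empty.
    """
    if len(cs) == 0:
        return cs
    mean = float(cs.areas.mean())
    return ContourSet(contours=tuple(c for c in cs if c.area_px >= mean))


def total_area(cs: ContourSet) -> float:
    """Sum of member contour areas in px^2 (0.0 for an empty set)."""
    return float(cs.areas.sum()) if len(cs) else 0.0
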