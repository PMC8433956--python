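"""End-to-end wound segmentation and measurement on a single photograph.

Stage sequence (each intermediate is retained under its letter key):

    a  grayscale conversion
    b  box blur (19 x 19 by default)
    c  Otsu binarisation + inversion — wound white on black
    d  small foreground shapes removed (contour area < 50 px^2)
    e  dilation with the 11 x 11 elliptical structuring element
    f  erosion with the same element (e + f = morphological closing)
    g  Canny edges of the closed mask
    h  dilation of the edges (merges fragmented boundary pieces)
    i  final mask: regions of h whose contours survive the area filters

The measurement then traces all contours of stage h, discards those below
``min_contour_area``, drops those below the mean area of the survivors'
contour set, sums what remains, and converts to cm^2 via the DPI arithmetic
in :mod:`woundarea.units`.

Two caveats the caller should know about.  First, tracing the *dilated* edge
band (stages g-i) reports the band's outer boundary, which sits roughly half
an edge-dilation kernel outside the true wound rim; the pre-Canny area of the
closed mask (stage f) is logged alongside as ``closed_mask_area_px`` so both
figures are available.  Second, a constant image or an empty final contour
set is not an error: the result carries zero areas and a ``no wound
detected`` warning.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np

from . import contours as ct
from . import raster_ops as ro
from .errors import ConfigError, DegenerateHistogramError
from .io_metadata import ImageMetadata, read_image, write_image
from .units import WoundMeasurement, measure_wound

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]

STAGE_LABELS = ("a", "b", "c", "d", "e", "f", "g", "h", "i")


@dataclass(frozen=True)
class PipelineConfig:
    """Tunable parameters of the measurement pipeline (defaults as published)."""

    blur_kernel: int = 19
    morph_kernel: int = 11
    morph_shape: str = "ellipse"
    min_contour_area: float = 50.0
    canny_low: int = 100
    canny_high: int = 200
    edge_dilate_kernel: int = 11
    mean_area_filter: bool = True
    dpi_override: float | None = None
    # Minimum separation (gray levels) between the two Otsu class means of the
    # blurred image.  Below it the histogram is effectively unimodal — a blank
    # frame whose sensor noise Otsu would happily split into a giant phantom
    # "wound" — and the pipeline reports "no wound detected" instead.
    min_class_separation: float = 10.0

    def __post_init__(self) -> None:
        for name in ("blur_kernel", "morph_kernel", "edge_dilate_kernel"):
            k = getattr(self, name)
            if not (isinstance(k, int) and k >= 1 and k % 2 == 1):
                raise ConfigError(f"{name} must be an odd integer >= 1, got {k!r}")
        if self.min_contour_area < 0:
            raise ConfigError(f"min_contour_area must be >= 0, got {self.min_contour_area}")
        if not (0 < self.canny_low < self.canny_high < 256):
            raise ConfigError(f"need 0 < canny_low < canny_high < 256, "
                              f"got {self.canny_low}, {self.canny_high}")
        if self.dpi_override is not None and self.dpi_override <= 0:
            raise ConfigError(f"dpi_override must be positive, got {self.dpi_override}")
        if self.min_class_separation < 0:
            raise ConfigError(f"min_class_separation must be >= 0, got {self.min_class_separation}")

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        """Load overrides from a JSON object or flat ``key=value`` lines."""
        import json

        text = Path(path).read_text(encoding="utf-8").strip()
        if text.startswith("{"):
            raw: dict = json.loads(text)
        else:
            raw = {}
            for line in text.splitlines():
                line = line.split("#", 1)[0].strip()
                if not line:
                    continue
                if "=" not in line:
                    raise ConfigError(f"{path}: expected key=value, got {line!r}")
                key, value = (s.strip() for s in line.split("=", 1))
                raw[key] = value
        kwargs: dict = {}
        for key, value in raw.items():
            if key not in cls.__dataclass_fields__:
                raise ConfigError(f"{path}: unknown parameter {key!r}")
            f = cls.__dataclass_fields__[key]
            if f.type in ("int",):
                kwargs[key] = int(value)
            elif f.type in ("float",):
                kwargs[key] = float(value)
            elif f.type == "bool":
                kwargs[key] = value if isinstance(value, bool) else value.lower() in ("1", "true", "on", "yes")
            elif f.type == "float | None":
                kwargs[key] = None if value in (None, "", "none") else float(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


@dataclass
class PipelineResult:
    """Measurement, the nine intermediate images, and a per-stage log."""

    measurement: WoundMeasurement
    intermediates: dict[str, np.ndarray]
    log: dict = field(default_factory=dict)

    @property
    def no_wound(self) -> bool:
        return bool(self.log.get("warning") == "no wound detected")

    def save_intermediates(self, out_dir: str | Path, meta: ImageMetadata) -> list[Path]:
        """Write step_a.png ... step_i.png into ``out_dir``."""
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = []
        for label in STAGE_LABELS:
            img = self.intermediates[label]
            m = replace(meta, height_px=img.shape[0], width_px=img.shape[1])
            paths.append(write_image(out_dir / f"step_{label}.png", img, m))
        return paths


def _final_mask(mask_h: np.ndarray, survivors: ct.ContourSet) -> np.ndarray:
    """Stage i: keep only the regions of h whose outer contour survived filtering."""
    from scipy import ndimage

    fg = mask_h > 0
    if not fg.any() or len(survivors) == 0:
        return np.zeros_like(mask_h)
    labels, n = ndimage.label(fg, structure=np.ones((3, 3), dtype=bool))
    keep = np.zeros(n + 1, dtype=bool)
    for c in survivors:
        if not c.is_hole:
            x0, y0 = (int(v) for v in c.points[0])
            keep[labels[y0, x0]] = True
    return np.where(keep[labels], 255, 0).astype(np.uint8)


def run_pipeline(source: str | Path | np.ndarray,
                 cfg: PipelineConfig | None = None,
                 metadata: ImageMetadata | None = None) -> PipelineResult:
    """Run the full measurement pipeline on one image.

    ``source`` is either a path to a PNG/JPEG/TIFF file (metadata, including
    DPI, is read from it, honouring ``cfg.dpi_override``) or an in-memory
    uint8 pixel array, in which case ``metadata`` must be supplied.

    The run is deterministic: identical input bytes and configuration yield a
    byte-identical result.
    """
    cfg = cfg or PipelineConfig()
    if isinstance(source, (str, Path)):
        img, meta = read_image(source, dpi_override=cfg.dpi_override)
    else:
        if metadata is None:
            raise ConfigError("run_pipeline needs ImageMetadata when given a pixel array")
        img, meta = np.asarray(source), metadata
        if cfg.dpi_override is not None:
            meta = replace(meta, dpi_x=cfg.dpi_override, dpi_y=cfg.dpi_override)

    log: dict = {"config": vars(cfg).copy(), "metadata": meta.to_dict()}
    inter: dict[str, np.ndarray] = {}
    se = ro.structuring_element(cfg.morph_shape, cfg.morph_kernel)
    edge_se = ro.structuring_element(cfg.morph_shape, cfg.edge_dilate_kernel)

    inter["a"] = gray = ro.to_grayscale(img)
    inter["b"] = blurred = ro.box_blur(gray, cfg.blur_kernel)

    def no_wound(reason: str) -> PipelineResult:
        for label in STAGE_LABELS:
            inter.setdefault(label, np.zeros_like(gray))
        log["warning"] = "no wound detected"
        log["reason"] = reason
        m = measure_wound(0.0, meta.width_px * meta.height_px, meta.height_px,
                          meta.dpi_x, meta.dpi_y, width_px=meta.width_px)
        return PipelineResult(measurement=m, intermediates=inter, log=log)

    try:
        t, bright = ro.otsu_threshold(blurred)
    except DegenerateHistogramError:
        return no_wound("constant image after blurring")
    log["otsu_threshold"] = t
    mu0 = float(blurred[blurred <= t].mean())
    mu1 = float(blurred[blurred > t].mean())
    log["otsu_class_separation"] = mu1 - mu0
    if mu1 - mu0 < cfg.min_class_separation:
        return no_wound(f"histogram effectively unimodal "
                        f"(class separation {mu1 - mu0:.1f} gray levels)")
    inter["c"] = wound_mask = ro.invert(bright)

    cs_c = ct.find_contours(wound_mask)
    log["contours_initial"] = len(cs_c)
    inter["d"] = cleaned = ct.remove_small_shapes(wound_mask, cfg.min_contour_area)
    inter["e"] = dilated = ro.dilate(cleaned, se)
    inter["f"] = closed = ro.erode(dilated, se)
    # Pre-Canny reference area of the closed mask (see module docstring).
    cs_f = ct.find_contours(closed)
    log["closed_mask_area_px"] = ct.total_area(
        ct.ContourSet(tuple(c for c in cs_f if not c.is_hole)))

    inter["g"] = edges = ro.canny_edges(closed, cfg.canny_low, cfg.canny_high)
    inter["h"] = band = ro.dilate(edges, edge_se)

    cs_h = ct.find_contours(band)
    log["contours_final_raw"] = len(cs_h)
    cs_big = ct.ContourSet(tuple(c for c in cs_h if c.area_px >= cfg.min_contour_area))
    cs_kept = ct.filter_by_mean_area(cs_big) if cfg.mean_area_filter else cs_big
    log["contours_final_kept"] = len(cs_kept)
    log["kept_contour_areas_px"] = [c.area_px for c in cs_kept]

    if len(cs_kept) == 0:
        return no_wound("no contour above the minimum area")

    wound_px = ct.total_area(cs_kept)
    inter["i"] = _final_mask(band, cs_kept)

    total_px = meta.width_px * meta.height_px
    wound_px_clipped = min(wound_px, float(total_px))  # shoelace area cannot exceed frame
    measurement = measure_wound(wound_px_clipped, total_px, meta.height_px,
                                meta.dpi_x, meta.dpi_y, width_px=meta.width_px)
    log["wound_area_px"] = wound_px
    return PipelineResult(measurement=measurement, intermediates=inter, log=log)
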