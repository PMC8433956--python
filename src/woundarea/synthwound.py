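"""Synthetic wound photographs with exact ground truth.

No clinical wound photographs ship with this package, so the pipeline is
validated against generated scenes that emulate what the method was designed
for: a dark, roughly convex lesion on a lighter skin-tone background,
photographed at a known DPI, with sensor noise and optionally some unrelated
small dark specks (dirt, moles) and a lateral illumination gradient.

What the generator reproduces:

* lesions as rasterised ellipses or smoothed random blobs (low-order radial
  harmonics), dark red on a skin-tone background, with a luma contrast large
  enough for a bimodal histogram (the regime the Otsu stage assumes);
* per-channel additive Gaussian sensor noise (sigma 8 by default), clipped
  to [0, 255];
* physical-resolution metadata (300 DPI by default) embedded on write.

What it deliberately does not reproduce: skin texture, specular glare,
perspective and camera-distance effects, or gradual wound-edge transitions.
Pipeline accuracy on these scenes is therefore an upper bound on clinical
accuracy, not an estimate of it.

Everything is reproducible: geometry is evaluated at pixel centres with pure
integer/float arithmetic, and all randomness comes from ``numpy``'s PCG64
generator seeded from the scene specification.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from . import contours as ct
from .errors import SpecError
from .io_metadata import ImageMetadata, write_image
from .units import measure_wound

__all__ = ["Lesion", "SyntheticWoundSpec", "GroundTruth", "generate", "make_fixture_suite"]

# Default palette: medium skin tone and a dark wound-bed red (luma 178 vs 48,
# a 130-level contrast — comfortably above the 60 the Otsu stage needs).
SKIN_RGB = (210, 170, 140)
WOUND_RGB = (90, 30, 30)

_LUMA = np.array([0.299, 0.587, 0.114])


def _luma(rgb) -> float:
    return float(np.dot(_LUMA, rgb))


@dataclass(frozen=True)
class Lesion:
    """One lesion: an axis-aligned ellipse or a smoothed random blob.

    For ``shape="blob"`` the boundary radius is ``r(theta) = a * (1 + sum_k
    amp_k * cos(k*theta + phase_k))`` with 2-4 low-order harmonics drawn from
    the scene's generator; ``semi_axes`` then gives the base radius twice.
    """

    center: tuple[float, float]          # (x, y) pixel coordinates
    semi_axes: tuple[float, float]       # (a, b); for blobs a == b == base radius
    shape: str = "ellipse"               # "ellipse" | "blob"
    rgb: tuple[int, int, int] = WOUND_RGB


@dataclass(frozen=True)
class SyntheticWoundSpec:
    """Full description of one synthetic scene."""

    canvas: tuple[int, int] = (1024, 706)            # (width, height) px
    dpi: float = 300.0
    background_rgb: tuple[int, int, int] = SKIN_RGB
    noise_sigma: float = 8.0
    lesions: tuple[Lesion, ...] = ()
    distractors: int = 0                             # small dark specks
    illumination_gradient: float = 0.0               # peak-to-peak luminance ramp, gray levels
    seed: int = 0
    margin: int = 11                                 # required lesion clearance, px

    def validate(self) -> None:
        w, h = self.canvas
        if w < 1 or h < 1:
            raise SpecError(f"canvas must be positive, got {self.canvas}")
        bg = _luma(self.background_rgb)
        for les in self.lesions:
            cx, cy = les.center
            a, b = les.semi_axes
            if a <= 0 or b <= 0:
                raise SpecError(f"lesion semi-axes must be positive, got {les.semi_axes}")
            reach_a, reach_b = (a, b) if les.shape == "ellipse" else (1.5 * a, 1.5 * b)
            if not (reach_a + self.margin <= cx <= w - 1 - reach_a - self.margin and
                    reach_b + self.margin <= cy <= h - 1 - reach_b - self.margin):
                raise SpecError(f"lesion at {les.center} exceeds the canvas margin")
            if bg - _luma(les.rgb) < 60:
                raise SpecError(
                    f"lesion luma {_luma(les.rgb):.0f} is less than 60 levels below "
                    f"background {bg:.0f}; the threshold stage cannot separate them")

    def to_dict(self) -> dict:
        return {
            "canvas": list(self.canvas), "dpi": self.dpi,
            "background_rgb": list(self.background_rgb),
            "noise_sigma": self.noise_sigma,
            "lesions": [{"center": list(l.center), "semi_axes": list(l.semi_axes),
                         "shape": l.shape, "rgb": list(l.rgb)} for l in self.lesions],
            "distractors": self.distractors,
            "illumination_gradient": self.illumination_gradient,
            "seed": self.seed, "margin": self.margin,
        }


@dataclass(frozen=True)
class GroundTruth:
    """Exact lesion geometry of a generated scene, before noise."""

    mask: np.ndarray                 # {0, 255}, true lesion pixels
    true_area_px: int                # pixel count
    true_contour_area_px: float      # shoelace area of the traced boundaries
    true_area_cm2: float             # contour area converted by the DPI arithmetic

    def summary(self) -> dict:
        return {"true_area_px": self.true_area_px,
                "true_contour_area_px": self.true_contour_area_px,
                "true_area_cm2": self.true_area_cm2}


def _lesion_mask(les: Lesion, width: int, height: int, rng: np.random.Generator) -> np.ndarray:
    cx, cy = les.center
    a, b = les.semi_axes
    yy, xx = np.mgrid[0:height, 0:width].astype(np.float64)
    dx, dy = xx - cx, yy - cy
    if les.shape == "ellipse":
        return (dx / a) ** 2 + (dy / b) ** 2 <= 1.0
    if les.shape == "blob":
        n_harm = int(rng.integers(2, 5))
        orders = np.arange(2, 2 + n_harm)
        amps = rng.uniform(0.03, 0.12, size=n_harm)
        phases = rng.uniform(0, 2 * np.pi, size=n_harm)
        theta = np.arctan2(dy, dx)
        radius = a * (1.0 + sum(amp * np.cos(k * theta + ph)
                                for k, amp, ph in zip(orders, amps, phases)))
        return np.hypot(dx, dy) <= radius
    raise SpecError(f"unknown lesion shape {les.shape!r}")


def generate(spec: SyntheticWoundSpec, *, validate: bool = True
             ) -> tuple[np.ndarray, ImageMetadata, GroundTruth]:
    """Render a scene: RGB pixels, metadata, and exact ground truth.

    The truth mask is the rasterised lesion set *before* noise and
    distractors; ``true_contour_area_px`` is measured by the same border
    following used downstream, so generator truth and pipeline output share
    one area convention.  ``validate=False`` skips the contrast/margin checks
    so documented hard cases (e.g. low-contrast scenes) can still be rendered.
    """
    if validate:
        spec.validate()
    width, height = spec.canvas
    rng = np.random.default_rng(spec.seed)

    img = np.empty((height, width, 3), dtype=np.float64)
    img[:] = spec.background_rgb
    if spec.illumination_gradient:
        ramp = np.linspace(-spec.illumination_gradient / 2,
                           spec.illumination_gradient / 2, width)
        img += ramp[None, :, None]

    lesion_mask = np.zeros((height, width), dtype=bool)
    for les in spec.lesions:
        m = _lesion_mask(les, width, height, rng)
        img[m] = les.rgb
        lesion_mask |= m

    if spec.distractors:
        # Small dark specks placed away from every lesion.
        yy, xx = np.mgrid[0:height, 0:width]
        keepout = ndimage.binary_dilation(lesion_mask, iterations=12) if lesion_mask.any() \
            else np.zeros_like(lesion_mask)
        for _ in range(spec.distractors):
            for _attempt in range(100):
                r = float(rng.uniform(1.5, 4.0))
                x = float(rng.uniform(r + 1, width - r - 2))
                y = float(rng.uniform(r + 1, height - r - 2))
                speck = (xx - x) ** 2 + (yy - y) ** 2 <= r * r
                if not (speck & keepout).any():
                    img[speck] = (60, 40, 40)
                    break

    if spec.noise_sigma > 0:
        img += rng.normal(0.0, spec.noise_sigma, size=img.shape)
    pixels = np.clip(np.floor(img + 0.5), 0, 255).astype(np.uint8)

    meta = ImageMetadata(width_px=width, height_px=height, dpi_x=spec.dpi, dpi_y=spec.dpi)
    mask255 = np.where(lesion_mask, 255, 0).astype(np.uint8)
    true_area_px = int(lesion_mask.sum())
    if true_area_px:
        cs = ct.find_contours(mask255)
        contour_area = ct.total_area(ct.ContourSet(tuple(c for c in cs if not c.is_hole)))
        cm2 = measure_wound(contour_area, width * height, height,
                            spec.dpi, spec.dpi, width_px=width).wound_area_cm2
    else:
        contour_area, cm2 = 0.0, 0.0
    truth = GroundTruth(mask=mask255, true_area_px=true_area_px,
                        true_contour_area_px=contour_area, true_area_cm2=cm2)
    return pixels, meta, truth


def _suite_specs(n: int, seed: int) -> list[tuple[str, SyntheticWoundSpec, bool]]:
    """(name, spec, expected_failure) triples cycling through the scenario kinds."""
    rng = np.random.default_rng(seed)
    out = []
    kinds = ("single", "multi", "distractor", "low_contrast")
    for i in range(n):
        kind = kinds[i % len(kinds)]
        sub = int(rng.integers(0, 2 ** 31 - 1))
        w, h = 640, 480
        if kind == "single":
            a = float(rng.uniform(60, 120))
            b = float(rng.uniform(0.6, 1.0)) * a
            lesions = (Lesion(center=(w / 2, h / 2), semi_axes=(a, b)),)
            spec = SyntheticWoundSpec(canvas=(w, h), lesions=lesions, seed=sub)
            xfail = False
        elif kind == "multi":
            lesions = (
                Lesion(center=(w * 0.3, h * 0.4), semi_axes=(70, 55)),
                Lesion(center=(w * 0.72, h * 0.62), semi_axes=(55, 45), shape="blob"),
            )
            spec = SyntheticWoundSpec(canvas=(w, h), lesions=lesions, seed=sub)
            xfail = False
        elif kind == "distractor":
            lesions = (Lesion(center=(w / 2, h / 2), semi_axes=(90, 70), shape="blob"),)
            spec = SyntheticWoundSpec(canvas=(w, h), lesions=lesions, distractors=5,
                                      illumination_gradient=12.0, seed=sub)
            xfail = False
        else:  # low contrast: below the separability the threshold stage needs
            lesions = (Lesion(center=(w / 2, h / 2), semi_axes=(80, 60),
                              rgb=(196, 158, 120)),)
            spec = SyntheticWoundSpec(canvas=(w, h), lesions=lesions, seed=sub)
            xfail = True
        out.append((f"{i:03d}_{kind}", spec, xfail))
    return out


def make_fixture_suite(out_dir: str | Path, n: int, seed: int) -> dict:
    """Write ``n`` synthetic fixtures plus a JSON manifest into ``out_dir``.

    Scenarios cycle through single-lesion, two-lesion, distractor-laden and
    low-contrast scenes; the last kind is flagged ``expected_failure`` in the
    manifest (its contrast is below what the threshold stage can separate, a
    documented hard case, not a target).  Re-running with the same arguments
    reproduces the files bit for bit.
    """
    if n < 1:
        raise SpecError(f"fixture count must be >= 1, got {n}")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    entries = []
    for name, spec, xfail in _suite_specs(n, seed):
        # Low-contrast scenes bypass the spec validator's contrast floor on
        # purpose: they document the failure mode.
        pixels, meta, truth = generate(spec, validate=not xfail)
        fname = f"wound_{name}.png"
        write_image(out_dir / fname, pixels, meta)
        entries.append({"file": fname, "spec": spec.to_dict(),
                        "truth": truth.summary(), "expected_failure": xfail})
    manifest = {"n": n, "seed": seed, "entries": entries}
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2), encoding="utf-8")
    return manifest
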