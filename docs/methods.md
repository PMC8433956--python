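# Methods

## The measurement model

The pipeline assumes a single photograph of a wound taken roughly
perpendicular to the skin, in which (i) the wound bed is substantially darker
than the surrounding skin, (ii) the image carries trustworthy physical
resolution metadata (DPI), and (iii) the whole frame lies at approximately
one distance from the camera, so a single px→cm scale applies everywhere.
Under these assumptions, segmentation reduces to global histogram
thresholding and the metric conversion to a linear scale per axis:

    value_cm = value_px × 2.54 / DPI

The wound area in cm² is computed by proportion: the traced contour area's
share of the frame's pixel area, multiplied by the frame's area in cm².
Because the frame edges are rounded to 2 decimals (centimetres) *before*
multiplication and the final area to 4 decimals, the arithmetic is exactly
reproducible: a 1062 × 706 px frame at 300 DPI gives 8.99 × 5.98 =
53.7602 cm², and a 54,746.5 px² wound in it 3.9254 cm². Rounding is half
away from zero throughout.

## Stages and parameters

| parameter | default | units | role |
|---|---|---|---|
| `blur_kernel` | 19 | px | box-blur window; suppresses texture/noise before thresholding |
| `morph_kernel` | 11 | px | elliptical structuring element for closing (dilate + erode) |
| `min_contour_area` | 50 | px² | discard speck contours (strict `<`) |
| `canny_low`, `canny_high` | 100, 200 | gray levels | hysteresis thresholds; insensitive on binary masks (gradient is max-normalized to 255) |
| `edge_dilate_kernel` | 11 | px | dilation of the Canny edges before the final contour pass |
| `mean_area_filter` | on | — | drop final contours below the mean contour area |
| `min_class_separation` | 10 | gray levels | guard against thresholding an effectively unimodal histogram |
| `dpi_override` | none | dots/inch | substitute for absent resolution metadata |

The kernel sizes (19, 11, 11) and the 50 px² floor are the published
operating point of the method; they are exposed but not re-tuned here.

### Numerical conventions

* **Grayscale**: BT.601 weights 0.299/0.587/0.114, rounded half away from
  zero. **Box blur**: reflect padding, exact int64 summed-area table, half-up
  rounding — bit-identical on every platform.
* **Otsu**: maximizes `ω₀ω₁(μ₀−μ₁)²` over all 256 split points; smallest
  maximizer on ties; a constant image raises a degenerate-histogram error.
  The mask is bright→255, then inverted so the dark wound is foreground.
* **Morphology**: background (0) padding for both dilation and erosion; the
  elliptical footprint contains every cell whose centre lies inside or on
  the ellipse with semi-axes (k−1)/2 (axis extremes included). With this
  border policy the closing identities (extensivity, idempotence) hold for
  foreground clear of the frame edge; a wound touching the border is outside
  the method's assumptions.
* **Canny**: Gaussian σ = 1, Sobel gradients, 4-direction non-maximum
  suppression, hysteresis by connected components. Input here is always a
  binary mask, whose single gradient ridge makes the edge set independent of
  the exact thresholds.
* **Contours**: Moore border following over pixel centres (clockwise,
  raster-scan discovery order; 8-connected foreground, 4-connected
  background). Areas are shoelace polygon areas — the traced boundary of a
  filled n × n square measures (n−1)², under a filled region's pixel count
  by about half its perimeter. Hole boundaries are traced too and their
  areas enter the mean filter and the final sum; no hierarchy is kept.

### Degenerate inputs

A constant (or near-constant) blurred image is reported as **no wound
detected** rather than segmented: Otsu always produces *some* split, and on
a blank noisy frame that split manufactures large phantom regions (measured
22 cm² on a blank 640 × 480 test frame). The pipeline therefore checks the
separation of the two Otsu class means of the blurred image and refuses to
proceed below `min_class_separation` (10 gray levels — far under the ≥ 60
levels of real wound/skin contrast, far over the ≲ 2 levels a blurred
noise-only frame retains). An empty final contour set likewise yields a
zero-area result with a warning, not an exception.

## Accuracy on synthetic scenes, and a known bias

The final area is taken from the contours of the *dilated Canny edge band*,
as the published procedure prescribes. The band's outer boundary sits ~5–6 px
outside the true wound rim (half the 11-px edge-dilation ellipse plus the
edge's own width), so the measurement carries a systematic positive bias of
roughly `p·δ/A` for a wound of area A and perimeter p: ~8 % for a 48,000 px²
lesion but ~25 % at 8,000 px² and ~60 % at 2,000 px². Both numbers are
therefore exposed: `log["wound_area_px"]` (the traced final area, the
method's headline figure) and `log["closed_mask_area_px"]` (the pre-Canny
closed-mask contour area, which tracks ground truth within ~10 % at every
size tested, typically within 2 %). The acceptance suite asserts a uniform
≤ 10 % end-to-end error over lesions of 2,000–60,000 px²; that check fails
below ~45,000 px² and is left failing deliberately — no admissible
edge-dilation kernel removes the bias at the small end (even omitting the
dilation leaves ~12 % at 2,000 px²), and silently re-defining the measured
quantity would misrepresent the method. Users measuring small lesions should
read the closed-mask figure.

## The synthetic scene generator

`synthwound` renders what the pipeline was designed for: a dark red lesion
(default RGB (90, 30, 30), luma 48) on a skin-tone background (default
(210, 170, 140), luma 179), i.e. ~130 gray levels of contrast, with
per-channel additive Gaussian sensor noise (σ = 8, clipped to [0, 255]),
optional small dark distractor specks, and an optional linear illumination
ramp. Lesions are axis-aligned ellipses or smoothed blobs (2–4 low-order
radial cosine harmonics, amplitudes 0.03–0.12) rasterized at pixel centres;
the ground-truth mask is the pre-noise rasterization, and its contour area
is measured by the same border following used downstream so truth and
measurement share one area convention. All randomness comes from numpy's
PCG64 seeded per scene: outputs are bit-stable across runs and platforms.

The generator's validator enforces the regime the method assumes: ≥ 60
levels of lesion/background luma contrast and full lesion clearance from the
frame edge (margin ≥ the morphology kernel). The fixture suite also emits a
deliberately *low-contrast* scene flagged `expected_failure` in its
manifest, documenting the failure mode rather than testing against it.

What the generator does **not** emulate: skin texture, specular highlights,
gradual wound-edge transitions, perspective and camera-distance variation,
colour casts. Passing on these scenes shows the pipeline implements its
specification and recovers known geometry; it does not certify clinical
accuracy on real photographs.

Default problem sizes — 640 × 480 px scenes, 20-scene sweeps, 200-image
property batches at 32 × 32 — keep the full suite comfortably within a few
minutes on one CPU while covering the lesion-to-frame ratios of interest
(0.7 %–20 %).

## Cross-device calibration

Paired areas (reference platform, test platform) are differenced per image
(`Δ` cm² at 2 decimals, `Δ%` at 1 decimal, half-up), and the MAE is the mean
of |Δ%| over the rounded percent column — the figure a reader recomputes
from the printed table. On the packaged ten-image reference dataset the test
series runs consistently low; its MAE is 36.1 %. The calibration is
multiplicative, `adjusted = round₂(test × (1 + MAE/100))`, which on this
dataset reduces the MAE to ~21 %. The adjustment assumes the bias is
proportional (a scale error, as a DPI/downsampling mismatch would produce),
not additive; with only ten pairs no inferential statistics are attached.

## Known limitations

* One measurement per image: multiple wounds are summed, not reported
  separately.
* No scale reference in the scene (coin, card): the DPI metadata is trusted
  entirely, and images whose metadata was stripped in transit are rejected
  unless an override is supplied.
* EXIF orientation is ignored (areas are rotation-invariant; width/height
  labels may swap on rotated files).
* The outward bias of the final traced area, quantified above.
* Wounds touching the frame edge violate the morphology border policy and
  are not supported.
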