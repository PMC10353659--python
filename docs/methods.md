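# Methods

## Canopy model

A canopy is generated from one point of a box-shaped parameter space.
Plants sit on a regular row grid: rows are `row_spacing` (m) apart, the
within-row spacing is chosen so the realized plant count equals
`round(plant_density × plot area)`, and every plant receives seeded
uniform positional jitter up to `plant_jitter` (m). Each plant carries
`tillers_per_plant × leaves_per_tiller` leaves.

A leaf is a triangulated ribbon over an arc midrib: the midrib leaves its
base at `leaf_inclination` degrees above horizontal and its tangent angle
decreases linearly with arc length, sweeping a total of
`leaf_curvature × 90°` over the leaf length — curvature 0 is a straight
blade, curvature ≳ 2 folds the tip below its base. The arc has a closed
form (integrals of cos/sin of a linear angle), which the geometry tests
exploit. The width profile rises linearly from 0 to `leaf_max_width` at
30 % of the length and tapers to 0 at the tip, so the analytic blade area
is `0.5 × length × width`; the 16-segment mesh reproduces it within 5 %.
Leaves that droop below the ground plane are clamped to z = 0. Growth
stage `s` of `n` scales organ counts and leaf dimensions by `s/n`, making
scene leaf area non-decreasing in stage. Per-leaf size/orientation/color
variation is keyed on stable (seed, plant, tiller, leaf) indices, so
scenes are deterministic and adding plants or stages never perturbs
existing leaves.

This parametric model intentionally replaces a physiological
plant-architecture model: it exposes exactly the structural controls that
drive image appearance (density, arrangement, inclination, curvature,
stage) with testable closed-form limits, at the cost of botanical
realism (no phyllotaxis rules, no senescence, no ears/panicles).

## Parameter spaces and sampling

Two bundled spaces (both user-replaceable via YAML):

- `default_space` — the full-density study space: plant density 40–300 m⁻²
  (wheat) / 40–120 m⁻² (rice), row spacing 0.12–0.20 m (wheat) /
  0.18–0.30 m (rice), 1–8 tillers, 2–6 leaves per tiller, leaf length
  0.12–0.30/0.45 m, width 6–18 mm, inclination 25–85°, curvature 0–2.5,
  height 0.2–1.0 m, plus hue/saturation scalars. Ranges were chosen once
  to span sparse seedling to near-closed canopies under the ≤2 m,
  sub-millimeter-GSD capture regime.
- `low_fidelity_space` — identical structure but density 5–25 m⁻² and
  1–2 tillers × 2–3 leaves, used by the bulk protocol so thousands of
  scenes render quickly on one CPU. Problem sizes in the bulk protocol
  (plot 0.6 m × 0.6 m) were likewise fixed as part of the protocol.

Sampling is Latin-hypercube (scipy `qmc.LatinHypercube`): for each
dimension the n draws occupy the n equal-probability strata exactly once;
log-scaled dimensions stratify in log10 space. Integer fields (organ
counts) are rounded at materialization. Each sampled point is replicated
across all growth stages downstream.

## Rendering

Deterministic z-buffer rasterization (numba kernels) through a pinhole
camera: horizontal FOV, square images, pixel (0,0) top-left, pixel
centers at half-integers, depth as 1/z interpolated linearly in screen
space. Triangles with a vertex at or behind the near plane (1 mm) are
dropped rather than clipped — scenes are designed to lie in front of the
camera. Ground sample distance at image center is
`1000 · 2 · (h/cos i) · tan(fov/2) / resolution` mm/pixel.

Coverage is resolved on a 4×4 subpixel grid per pixel. A mask pixel is
green iff the majority (≥ 9/16) of its subsamples hit a green-vegetation
triangle; an exact 8/8 tie goes to background. The RGB pixel averages its
subsample shading, so image and label come from one geometry pass and the
label is independent of illumination and of the color seed.

Shading is double-sided Lambertian: intensity
`d + (1−d)·|n·s|·lit` with `d` the diffuse fraction, `s` the sun
direction, and `lit` a hard-shadow term from an orthographic 1,024²
sun-view depth map (sunny condition only, optional). Sunny requires
d < 0.5, cloudy d ≥ 0.8. Leaf color is a per-leaf green (HSV-derived from
the hue/saturation parameters) with seeded per-facet brightness variation
(±15 %); the wheat background is mottled brown soil (three-octave value
noise on the ground plane, shaded per pixel center since it varies
smoothly); the rice background is a flat light-gray water surface with a
sun-glint specular lobe (Phong exponent 60). Output is sRGB 8-bit with
clamp tone mapping.

## Dataset handling

Tiling center-crops to the largest multiple of the tile size (512 by
default) and cuts a non-overlapping grid; masks tile identically, so
tiles reassemble to the crop exactly and the mean tile GF equals the
crop GF. Splits are seeded and grouped by source image — all tiles of one
source share a split — to prevent spatial leakage. `export_unpaired`
writes the `trainA`/`trainB` layout consumed by unpaired image
translation tools; it refuses to overwrite non-empty folders unless
forced. Masks are PNG 0/255; any nonzero value reads as green, with a
warning.

## Segmentation

The bundled baseline thresholds ExG = 2G − R − B (raw digital numbers,
not chromaticity) with Otsu's method: 256 histogram bins over the value
range, threshold at the bin edge maximizing between-class variance,
pixels strictly above the threshold are green. Ties — including the
floating-point-flat plateau that arises when the histogram has an empty
gap between modes — break to the smallest threshold (tolerance 1e-10
relative). Constant-color images have no threshold; the segmenter then
returns all-background. Because ExG is linear in the channels, uniform
brightness scaling rescales the histogram and leaves the mask unchanged
up to bin re-quantization at mask boundaries.

Deep segmenters are deliberately adapters, not implementations: any
executable that maps an RGB PNG to a binary mask PNG can be evaluated via
`run_external`, with per-image rejection of malformed outputs (wrong
dimensions, non-binary values) while the run continues.

## Metrics

Green vegetation is the positive class throughout. Confusion entries are
proportions of all pixels and pool across images by pixel-weighted
averaging (exactly equivalent to counting over the concatenation). R² is
the standard coefficient of determination 1 − Σ(fᵢ−yᵢ)²/Σ(yᵢ−ȳ)²,
undefined (reported as such) for a constant reference. The image distance
is normalized per digital number and per pixel,
`sqrt(mean(((x−y)/255)²))`, bounding it to [0, 1] regardless of image
size; the set-level domain gap is the mean over seeded random cross-set
pairs (with standard error). To make the gap independent of argument
order, the two index streams are assigned by a content hash of each set,
so gap(A,B) = gap(B,A) at the same seed. GF series sort by timestamp and
average duplicate timestamps.

## Uncertainty analysis

Error maps assign each pixel TP/TN/FP/FN; class proportions agree with
the confusion counts exactly by construction (one shared definition).
Feature distributions per class use Gaussian KDE with Scott's-rule
bandwidth, evaluated on a 256-point uniform grid spanning
[min − 3bw, max + 3bw] (≥ 99.7 % of the mass, so the trapezoidal
integral is 1 within 2 %). An empty class returns an explicit
absent-class result. Pixels are pooled across images before density
estimation. L* uses sRGB with the standard piecewise transfer curve under
D65 (skimage). Overlays use an injective palette (TP green, TN dark gray,
FP red, FN blue) and decode losslessly back to the class map.

## What the simulator does and does not emulate

It emulates: the stated capture regime (camera ≤ 2 m above canopy,
horizontal FOV up to 85°, nadir to 45° views, 1,024² images tiled to
512²), the two-class labeling convention, sunny/cloudy illumination with
canopy shadows, crop-specific backgrounds (soil vs specular water), and
structural diversity via the sampled space. It does not emulate: sensor
noise, lens distortion, senescent organs (senescent pixels would be
background by the labeling convention but are simply never generated),
weeds, ears/panicles, or photorealistic global illumination. Baseline
scores on clean synthetic scenes are therefore upper bounds: they show
the pipeline is internally consistent, not that any segmenter will reach
the same numbers on field images, where the domain gap (quantified here
only between illumination conditions) is far larger.

## Numerical choices and degenerate inputs

Supersampling fixed at 4×4 with ties to background; near-plane 1 mm;
shadow-map bias 5e-3 m; empty scenes, zero-density canopies and n = 0
sampling are legal no-ops; image smaller than the tile is an error at
tiling and a reported skip in the CLI; F1 is defined 0 when no green
exists in either mask; constant references make R² undefined rather than
±inf. The CLI derives per-stage seeds as
`SeedSequence((global_seed, stage_index))`, so reruns of a single stage
reproduce without replaying the pipeline.
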