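# Methods

This note records the models behind `agrocam`, the parameters that
matter, what the synthetic scenes do and do not emulate, and the choices
made where the design was genuinely open.

## Camera model and the pixel-resolution proxy

World frame: origin on the ground beneath the pinhole, X forward, Y
left, Z up.  The pose composes yaw β (about world Z), pitch α (about
the camera x axis; α is measured **from the horizontal**, so α = 90°
points straight down — note that several common conventions measure
from the vertical), then roll θ (about the optical axis).  Roll and yaw
default to zero (level terrain, correct guidance).  The ROI distance
*d* is measured horizontally from the camera's ground projection to the
**near edge** of the target, which is centred laterally on the
direction of travel; this keeps *d* independent of α.  Pixel
coordinates have their origin at the top-left corner, u rightward, v
downward, with pixel (i, j) occupying the unit square centred at
(i + 0.5, j + 0.5).

The resolution proxy *n* of an arrangement is the area in pixels of the
projected ground quad.  The projection maps the four ground corners to
pixel space and takes the shoelace area of the straight-edged quad
(optionally intersected with the sensor box via polygon clipping); a
rasterised pixel-centre count is available as an independent
cross-check, and the two agree within a fraction of a percent at survey
scales.  Straight quad edges slightly under-represent the curved images
of ground lines under the equidistant model; at survey geometries the
renderer's exact per-pixel count agrees with the quad area to ~0.1 %,
so the approximation is immaterial here.

### Radial projection: why equidistant by default

An ideal rectilinear pinhole (radius f·tanθ) magnifies off-axis ground
strongly (≈ sec³ of the off-axis angle).  Checked against the packaged
125-point field survey, that model reproduces the distance trend, the
d = 3 m optimum and the pitch-30° dip, but *reverses* the measured
growth of n with mounting height at pitch 40–50°, and correlates at
r = 0.964.  The equidistant wide-angle law (radius f·θ, the standard
strong-barrel-distortion limit) reproduces **all** measured trends and
correlates at r ≈ 0.98.  Physically, the 10 mm lens covering a >50°
field on a 16 mm image circle is exactly the regime where barrel
distortion compresses corner magnification, so the equidistant law is
adopted as the package default and used consistently by the sweep, the
renderer and the cross-module checks; `projection="rectilinear"` remains
available and is exercised by closed-form tests (e.g. the nadir
similar-triangles example).  Magnitudes: equidistant simulated areas run
76–97 % of the measured counts; comparisons are therefore reported as
correlations and trends, not absolute areas.  No attempt is made to fit
an intermediate distortion polynomial — one parameter-free law suffices
for every qualitative claim, and no calibration data exist to fit more.

The measured survey's own agreement statistic ("0.0088 % average") is
not reproducible because the quantity's numerator and denominator are
undefined; this package reports Pearson correlation over all 125 cells
plus per-cell relative errors instead.

A further survey quirk, kept verbatim in the fixture: the five entries
of the d = 4.0 m / h = 225 cm row are printed with decimal points that
are thousands separators (74,236 …), and the "chosen arrangement"
pixel count 56,985 sits in the d = 4.5 m column although the narrative
calls it d = 4 m.  Derived statistics use the cell that contains the
printed number.

## Exposure control

State: exposure time E_t (µs) with band fractions a = 0.90, b = 0.98 of
the saturation level M = 255, and adjustment fraction p = 0.20.  One
step samples the white quadrant of the reference panel, takes
H = max(R̄, Ḡ, B̄), and applies: raise E_t by (1+p) if H < aM, lower by
(1−p) if H > bM, else keep.  The inequalities are implemented exactly as
stated, which makes H = bM a "keep" even though the band is written
[aM, bM); the discrepancy affects only the single boundary value.
Because b/a ≈ 1.089 < 1.2, ±20 % steps can straddle the band on a
static scene, so the loop carries max_iter (default 10) and a
`converged` flag instead of a termination guarantee; the full (E_t, H,
decision) trace is returned for diagnosis.

## Vignetting

The pattern P is the Euclidean distance from the image centre normalised
by the largest centre-to-corner distance — the only normalisation that
satisfies both stated boundary conditions (0 at the centre, 1 at the
corners).  Correction multiplies each channel by (1 + K·P) with defaults
K_r = 0.3, K_g = K_b = 0 (only red is attenuated by the filter).
Integer images are corrected in floating point and rounded half-up;
values above M clamp to M and clamp events are counted and logged.  The
renderer's forward model divides red by (1 + K·P), so the correction is
its exact inverse: round trips restore red within ±1 level wherever no
clamping occurred (verified over every unclipped pixel of rendered
frames).

## Segmentation

Fuzzy c-means with k = 2, fuzziness m = 2, tolerance 1e-4 on centre
movement, 300-iteration cap, initialised deterministically from the
per-channel 0.2/0.8 sample quantiles (order-invariant, seed-free); the
pixel *sampling* (default 2,000 pixels, uniform without replacement) is
seeded.  The centre with the larger green chromatic coordinate is the
vegetation centre; the global threshold is that centre's green fraction
G/(R+G+B), and a pixel is vegetation iff its own green fraction strictly
exceeds it (ties are background; zero-sum pixels are background).  The
comparison operates on a ratio, so classification is invariant to
uniform intensity scaling — the reason exposure errors harm it only
through noise and quantisation, not through brightness itself.  The
original clustering-derived threshold this follows is described only at
this level; whether it thresholded normalised or raw green is not
recoverable, and the normalised reading is implemented.

Bright-orange cardboard extraction is an HSV gate (hue 15–40°,
saturation ≥ 0.5, value ≥ 0.5 by default, all overridable) with an
optional largest-connected-component filter.

## Evaluation

PCC = (TW + TB)/(TW + TB + FW + FB), reported as a percentage.  Field
protocols discard the top third of each image (horizon, outside the
treated strip); `crop_bottom_two_thirds` keeps rows floor(H/3)…H−1 (the
rounding direction is a fixed convention).  The 2 × 2 condition grid
segments each member of an (under-exposed, adjusted) pair with and
without vignetting correction and averages PCC per condition over the
batch.  Ground truth for synthetic batches is the renderer's exact
vegetation mask — replacing the expert-curated, manually touched-up
truth used with real imagery, which software cannot reproduce.  With
exact truth and no human selection step, absolute PCC values are not
comparable to field-measured ones; only the ordering across conditions
is claimed, and the measured absolute values (66/74/83/91 on 25 real
pairs) are explicitly out of scope because those field images are not
deposited.

## The synthetic scenes

A scene is a flat field ray-cast per pixel against the ground plane:
soil background, crop rows 0.75 m apart (as in maize) running in the
direction of travel, seeded elliptical weed blobs between rows
(default density 0.10), optionally the 1 × 1 m orange cardboard and a
four-colour reference panel (white quadrant nearest-left).  The sensor
is linear in E_t, with in-sensor red vignetting (division by 1 + 0.3 P),
additive Gaussian noise (default sd 2 levels), half-up rounding and
clipping to 8 bits.  Truth masks are rendered from the same geometry
with no noise, and the vegetation/cardboard/panel masks are pairwise
disjoint by construction.

Colour statistics are chosen to reproduce the greenness structure real
field images show rather than poster-colour classes: soil
(115, 100, 78) (green fraction 0.34), dull greens for crop and weeds
(0.42–0.44), and a per-pixel left-skewed Beta(0.6, 1.4) dilution of
vegetation toward soil that emulates mixed boundary pixels, shading and
senescent material.  Under these statistics the learned global
threshold lands a few hundredths above the soil green fraction — the
regime in which corner red-attenuation pushes soil past the threshold
(the corner false-white failure) and in which under-exposure lets noise
and quantisation flip marginal pixels (the over-segmentation failure).
Both failure modes and their removal by the two corrections are then
emergent, not scripted: the 2 × 2 ordering holds across every seed
batch tested, with mean PCC spanning ≈ 72–89 %, close to the 66–91 %
range measured in the field.

What the scenes do **not** emulate: plant morphology and 3-D canopy
structure, shadows, specular soil, motion blur from vehicle
oscillation, perspective-dependent colour mixing at sub-pixel scale,
and real spectral responses.  Passing tests therefore demonstrate the
correctness and the qualitative behaviour of the pipeline, not
field-absolute accuracy numbers.

## Problem sizes and determinism

Full-resolution rendering (2336 × 1752) is supported; tests and the
acceptance script render at 1/4 scale (584 × 438) with the pixel pitch
scaled by the same factor, which preserves the field of view and keeps
a ten-pair 2 × 2 experiment under a minute.  Every stochastic component
(weed layout, soil texture, vegetation dilution, sensor noise, sampling,
ambient illumination across simulated days) is seeded; identical seeds
give bit-identical images, tables and reports.
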