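# Methods

## The measurement model

Transmission scans of a worm plate show dark worms (they absorb the
scanner's light) on a lighter agar background. Two scans taken 90 s apart
bracket the phototactic startle response: the first scan's light stimulates
live worms, the second catches them displaced. Every quantity the package
reports derives from this pair (or a longer series of such scans).

**Movement fraction.** For a worm region W segmented in the first scan and
the binarized difference image B of the aligned pair, the movement fraction
is m = |W ∩ B| / |W|, computed in integer pixel arithmetic and clamped to
[0, 1]. Geometrically, m is the fraction of the worm's original footprint
that changed appearance; it saturates once the worm has moved one body
length, so it measures responsiveness, not speed, and cannot distinguish a
worm that moved two body lengths from one that moved one. Mortality is
called by a strict threshold: dead iff m < 0.10. The boundary case m = 0.10
is alive. The 10 % floor exists to absorb residual noise in the difference
image; it is configurable but 0.10 is the validated default.

**Hysteresis binarization.** The difference image is thresholded at two
levels: pixels ≥ high seed regions, which grow through 8-connected pixels
≥ low. Defaults are noise-adaptive — low = 4·s, high = 8·s with
s = 1.4826 × MAD of the difference map (the robust normal-consistent noise
scale). On an exactly noise-free map (s = 0) the thresholds fall back to
half the smallest positive difference, retaining exactly the changed
pixels. Both thresholds can be overridden.

**Registration.** Sequential flatbed scans can shift by a few pixels
(carriage repositioning, plate handling) but cannot rotate or scale, so a
translation-only model is used: phase cross-correlation with 1/20-px
upsampled peak interpolation, bounded by a configurable maximum (50 px).
Integer shifts are undone exactly by rolling; subpixel residuals use linear
interpolation. Border pixels with no source data are invalidated via a mask
that the difference image consumes — never extrapolated. An affine model
was deliberately left out. Note one genuine degeneracy: a plate on which
*every* worm moves a full body length over a featureless background gives
phase correlation nothing static to lock onto; real plates always contain
static structure (plate edge, agar texture, dead worms).

**Segmentation.** A random forest (100 trees, fixed seed) classifies each
pixel from a multi-scale feature stack computed at σ ∈ {2, 4, 8, 16} px:
raw intensity, Gaussian blur, square mean (side 2σ+1), local variance,
all ordered Gaussian differences, the largest structure-tensor eigenvalue,
and a Lipschitz bottom-hat. The Lipschitz feature is the gap between the
inverted image and its lower Lipschitz cover with cone slope 1/(2σ) per
pixel, computed as an iterated 3×3 chamfer min-convolution; it lights up
dark structures narrower than the cone, which is exactly a worm body.
Membrane projections (oriented line means at 30° steps, patch 1,
thickness 19) are implemented but off by default: the upstream semantics
of those two numbers are ambiguous and our oriented-line reading is
flagged experimental. The probability map is cut at 0.5, and particle
analysis keeps 8-connected components with area in [200, 20000] px at
2400 dpi — an adult worm (~1 mm × 0.06 mm) covers roughly 500–900 px, and
the bounds filter both noise specks and fused clumps. Area is the only
particle filter; no circularity criterion is applied. A plain Otsu
threshold segmenter (`ThresholdSegmenter`) is provided for high-contrast
images and fast end-to-end tests.

**Morphometry.** A worm's length is derived from the morphological
skeleton of its mask. The raw statistic — longest geodesic between
skeleton endpoints with steps weighted 1 (orthogonal) and √2 (diagonal) —
is exposed as `skeleton_length` and is exact on the axis-aligned and
diagonal toy cases (24.0 for a 25-pixel run, 10√2 for an 11-pixel
diagonal). Taking the longest endpoint-to-endpoint path automatically
discards short side branches, which for an unbranched animal are thinning
artifacts. Two corrections are applied in `measure_region` because the raw
geodesic is a biased length estimator:

* the 1/√2 chamfer rule over-measures digital curves by up to ~8 % near
  22.5° orientations, so the reported length is the Euclidean length of
  the geodesic path after Gaussian smoothing of its vertex chain
  (σ = 1.2 samples, endpoints pinned) — exact on straight toys, nearly
  unbiased in between;
* thinning erodes up to about one half-width from each body end, so each
  path end is extended by ray-casting to the mask boundary less one
  half-width (the rounded cap's own radius, estimated as the median
  medial distance-transform value along the path), capped at 1.5
  half-widths.

On synthetic worms of 0.5–1.5 mm at 2400 dpi this keeps individual lengths
within ±5 % of the true centerline (mean error ≈ +1 %); the residual tail
is worst for short, strongly curved worms. Conversion to millimetres is
length × 25.4 / dpi.

**Abbreviated counting.** Live worms are counted without segmentation:
align, difference, hysteresis, then particle analysis of motion blobs. A
partially displaced worm leaves two blobs — the patch it vacated and the
patch it entered — separated by its unmoved mid-body, so a small closing
cannot merge them and plain blob counting double-counts. The default merge
therefore bridges difference blobs through dark (worm-occupied) pixels of
either scan: a moving worm's two crescents are connected by its own body,
while a static worm's body contains no difference pixels and is never
counted. Components are measured by their difference-pixel area (bounds
[50, 40000] px: lower than segmentation because a weak responder's blob
covers a fraction of its body, higher because a merged departure+arrival
particle covers up to two bodies). Plain closing (radius = worm
half-width, ~3 px at 2400 dpi) remains available via
`bridge_through_bodies=False` and is exercised in tests at both failure
extremes (radius 0 over-counts; large radii merge neighbors). Known
limitation: a large worm twitching just below the 10 % mortality threshold
can still leave a blob above the minimum area and be counted; the area
floor is the only guard, because the abbreviated algorithm has no per-worm
denominator.

**Probit dose–response.** Mortality counts at each concentration are
modeled as binomial with P(dead) = Φ(β₀ + β₁·x), x the dose (linear scale
by default — exposures are run across a linear concentration range — with
log10 optional). The fit is Fisher scoring with step halving, so the
log-likelihood is non-decreasing across iterations, converging when it
changes by < 1e-10 (max 100 iterations); it reproduces statsmodels' GLM
probit estimates to machine precision and a dense grid-search MLE to three
significant figures. LC50 = −β₀/β₁ (back-transformed on the log scale);
LC_p = (Φ⁻¹(p) − β₀)/β₁; standard errors come from the inverse Fisher
information with the delta method for LC50. Complete separation is
detected directly from the data (a dose threshold splitting all-alive from
all-dead); the fit then warns and adds a small quadratic coefficient
penalty (1e-4) so finite estimates are still returned, flagged
`penalized`. A flat response gives slope 0 and an invalid fit rather than
a fabricated LC50. No natural-response (Abbott) correction is applied.

**Fecundity, lifespan, habituation.** Fecundity: per-day means across
replicate plates with cumulative sums and normal-approximation 95 %
intervals (mean ± 1.96 SE). With only 3 replicates the normal interval
undercovers (a t-quantile would need 4.3); the interval is reported as the
conventional summary, not as a calibrated test. Lifespan: the mean of
individual death days, with the standard error taken across trial means
(the plate-replication convention); death days can be supplied directly or
inferred from a non-increasing daily live-count series by successive
differences. Habituation: a series of k scans yields k−1 intervals, each
scored like a mortality pair; the reported fraction is the share of
segmented worms with movement ≥ the response threshold (default 0.10).
Worms appearing only in the later scan of a pair are never scored.

## The synthetic-plate generator

The generator is the package's ground-truth instrument. It emulates the
imaging conventions of the assay — 16-bit grayscale at 2400 dpi, 90 s
inter-scan interval, 30–150 worms per 5.5 cm plate (enforced as
non-overlapping placements; a placement that cannot be satisfied raises
rather than silently overlapping) — with these choices:

* **Worm geometry**: the centerline is the graph of a two-term
  random-phase sinusoid (wavelengths L and L/2, amplitudes 4–12 % and
  1–5 % of body length L) along a random axis, rasterized with constant
  half-width (0.03 mm). The axis extent is solved from the cumulative arc
  length so the centerline's true length equals the sampled target
  (0.5–1.5 mm uniform by default), and the ground truth records the
  discretized centerline and its arc-length sum.
* **Motion**: between scans a worm slides along its own extended
  centerline — crude peristalsis that produces the partial self-overlap
  of real crawling. The slide distance is bisected until the realized
  moved fraction |m₁ \ m₂|/|m₁| matches the request within ±0.02 (exact
  0 for a request of 0). A request of 1.0 slides at least one body length
  until the masks are exactly disjoint; if the plate edge blocks that,
  the placement is resampled. Ground truth stores per-interval realized
  fractions and the alive flag (realized ≥ 0.10).
* **Intensity and noise**: flat agar background at 75 % of dynamic range,
  worms at 35 %, additive Gaussian sensor noise (σ = 0.5 % of range by
  default) clipped to range. An optional smooth background texture field
  (off by default, so the degenerate noise-free plate is exactly
  constant) exercises robustness. Non-worm artifacts are small ellipses
  of worm-like intensity but sub-worm area (< 100 px), static between
  scans. An optional integer plate shift is applied to later scans.
* **Determinism**: one `numpy` Generator seeded from the spec; identical
  spec + seed gives bit-identical images and ground truth.

What the generator does **not** emulate — and what passing tests therefore
do not establish about real scans: bacterial-lawn texture and condensation
artifacts; egg and L1-stage rendering (L1 is below the method's resolving
power); overlapping or touching worms (real dense plates require digital
untangling, out of scope); body-shape change during crawling beyond the
slide model; scanner-specific noise statistics (the Gaussian model is a
stand-in, not a claim about any particular scanner).

## Problem sizes and numerical choices

Tests and the acceptance script run on cropped tiles at full 2400 dpi
scale rather than whole 5.5 cm plates: a 1200-px tile (12.7 mm) carries
10 worms at the 150-per-plate density equivalent and 2 at the 30-per-plate
equivalent, and statistics are aggregated across tiles. The classifier is
trained once on a 600-px plate (2000 pixels per class) and applied to
held-out tiles from different seeds. Probit recovery uses the 7-dose ×
50-worm × 3-replicate design typical of the assay; lifespan simulation
uses 3 trials × 48 worms. The CLI exposes every threshold; all defaults
are stated above. Coordinates are (row, col), 0-based, origin top-left;
bounding boxes half-open — consistently across modules.

## Known limitations

* Only movement rate is measured; direction, speed and waveform are out of
  scope, as is identity tracking across scans or days.
* Worms present only in the second scan (edge immigrants) are not scored.
* The mortality rule misclassifies a live-but-unresponsive worm as dead by
  construction; that is a property of the assay, not the implementation.
* The probit module deliberately omits survival machinery beyond the
  mean-lifespan summary (no Kaplan–Meier or log-rank).
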