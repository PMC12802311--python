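# Methods

This note records the models, estimators, numerical choices and known
limitations behind `swarmetrics`, in the spirit of a methods appendix.

## The synthetic scene model

The generator emulates phase-contrast micrographs of a swarm monolayer's
expanding edge: dark constant-width tubes (cells) on a gray agar
background, with three deliberate nuisance structures — thin brighter
seams where cells touch (the "intercellular space" signal), faint
light-gray flagella-like filaments, and sub-µm debris specks.

**Cell geometry.** A cell is a tube of width *W* swept along a curved
backbone with hemispherical pole caps, so its total length is
*L = B + W* where *B* is the backbone arc length. Backbones are heading
random-walks: a smooth random heading profile (Gaussian-filtered noise,
cumulatively summed) is scaled by bisection until the arc/chord ratio
matches a sampled sinuosity target within 2%; the achieved ratio is
recorded as truth. This reproduces the linear-to-spiral shape range of
swarmer cells controllably. Cells are placed by rejection sampling
(largest first) with pixel-exact non-overlap; contact is allowed, and a
1-px seam on the lower-labeled side of each contact is rendered brighter
than background. Placement failure after 300 attempts raises an explicit
density error rather than silently dropping cells.

**Default study conditions** (all physical units; pixel size 0.1 µm/px,
giving ~8 px cell width, adequate for skeleton morphometrics):

- short cells: truncated normal, mean 2.8 µm, sd 0.7, support (1, 4] µm —
  a realistic vegetative-rod range; the 4 µm boundary separates cells
  shorter than one doubling from elongated swarmers;
- long cells: truncated normal over (4, 16] µm whose mean rises from
  5.5 µm (hour 2) to 9 µm (hour 6) and falls back, with the long-cell
  fraction 0.10 → 0.60 → 0.30 across the hour-2..8 presets (majority long
  at hour 6, when collective migration peaks);
- width: truncated normal 0.8 ± 0.05 µm on [0.6, 1.0]. The source
  populations show minimal width change over the cycle, but no numeric
  width distribution is available, so this is a documented placeholder;
- sinuosity: 1 + Exponential(0.03), capped at 1.3;
- debris: uniform length 0.3–1.0 µm (everything ≤ 1 µm is debris by
  definition); 40 specks per preset frame;
- filaments: 0.3 per 100 µm², drawn only on background;
- optics: Gaussian PSF (σ = 1 px) then additive Gaussian noise
  (sd 0.02 on a [0, 1] intensity scale).

**Fluorescence channel.** Per-cell intensity follows
*I = a·L + b + ε*, ε ~ N(0, σ²), with defaults a = 0.0276 a.u./µm,
b = 0.84336 a.u. and σ calibrated from a target population R² via the
simple-regression identity σ² = a²·Var(L)·(1 − R²)/R² (default target
0.3177 — a deliberately weak coupling). Cell pixels are rendered at
background + *I* with per-pixel noise but no PSF blur, so the measured
per-cell mean is an unbiased estimate of *I*; modeling fluorescence
blur/bleed-through is out of scope.

**What the generator does not emulate.** Uneven illumination, focus
drift, multi-layered regions, motility blur, Poisson shot noise, and
partial-volume effects at cell boundaries are absent. Passing tests
therefore demonstrate correctness of the algorithms under the stated
image model, not performance on any particular microscope's data; on
real data the classifier must be retrained from manual strokes, which is
the pipeline's intended use.

## Segmentation

Per-pixel features: Gaussian smoothings at σ ∈ {1, 2, 4, 8} px, Gaussian
gradient magnitude and Laplacian at each σ, and differences of Gaussians
between adjacent σ. The Laplacian is computed on the mean-subtracted
image so that a constant image yields exactly zero (the truncated LoG
kernel does not sum to zero). Feature order is fixed and versioned; a
σ = 0 entry contributes the identity feature only.

The classifier is a seeded random forest (100 trees, unlimited depth,
single-threaded for determinism), mirroring the FastRandomForest default
of trainable-segmentation tools. Annotations are sparse strokes, not
full masks; for synthetic scenes they are bootstrapped from ground truth
(cell interiors eroded by 1 px, background ≥ 2 px from any object, seams
plus filaments for the intercellular-space class), emulating a careful
human tracer. Binary masks threshold P(CELL) at 0.5 (configurable);
interspace and background both map to off, which is what splits touching
cells. Interior holes smaller than `min_hole_px` (default 30 px in the
pipeline) are filled so skeletons are not perforated.

## Morphometry

Per particle (8-connectivity components, labels in row-major first-pixel
order):

- **skeleton path**: the particle is thinned; the skeleton pixel graph
  (steps 1/√2) is swept twice with Dijkstra to find its longest geodesic
  path, which implicitly prunes side branches; the path's ends are then
  trimmed where the medial-axis radius falls below 0.9× the robust
  (75th-percentile) half-width, by at most one half-width per end — this
  removes thinning hooks at square ends and anchors the endpoints where
  the pole caps begin;
- **length** = trimmed geodesic + width (one half-width per cap). On
  straight rods 2–20 µm this is accurate to < 0.05 µm; on strongly
  curved sub-3 µm cells it is biased low by up to ~half a width;
- **width** = 2× mean distance-transform value along the trimmed path;
- **sinuosity** = geodesic/chord of the path after light smoothing
  (3-pixel moving average; raw pixel chains zigzag and would inflate
  both arc length and sinuosity). Particles whose path has < 2 px get
  sinuosity 1 and length = width. Sinuosity is floored at 1;
- **perimeter**: 4-direction Crofton estimate; **circularity**
  min(1, 4πA/P²) — capped because discrete perimeter estimators can push
  the ratio above 1 on small rasters;
- **filters**: area ≥ 1 µm² and circularity ≤ 0.9 inclusive, length
  > 1 µm strictly exclusive (objects of exactly 1 µm count as debris),
  edge-touching particles excluded. Tightening any single bound can only
  shrink the survivor set; survivors and rejects partition the input.

Merged neighbors that segmentation fails to separate are reported as
missed detections, not split; pole/septum detection is out of scope.

## Fluorescence normalization

Background is the arithmetic mean of the mean intensities of `n_boxes`
(default 4) square boxes of `box_size` (default 5 µm) placed uniformly
at random among positions containing no labeled pixel. "Cell-free" is
defined against the label image, not raw intensity, for auditability.
Boxes are drawn without replacement and non-overlapping placements are
preferred; overlap is permitted (and flagged in the audit record) only
if a non-overlapping draw fails, and the estimator errs out rather than
shrinking boxes when too few cell-free positions exist. Per-cell mean
intensity is mean(F − background) over the cell's pixels; negative
values (cells dimmer than background) are preserved.

## Population statistics

Quartiles use linear interpolation (type 7). Variance is the unbiased
sample variance; its 95% CI is a seeded nonparametric bootstrap
percentile interval (1,000 resamples by default). The percentile
bootstrap for a variance only attains its nominal coverage
asymptotically — for normal data it covers ~92% at n = 200 and ~95% at
n = 800 — so the calibration suite checks coverage at n = 800 per
repeat, which is well below the thousands of cells per time point the
pipeline produces in practice.

Pairwise comparisons use the two-sided Wilcoxon/Mann–Whitney rank-sum
test: exact enumeration of all pooled-rank splits (midranks, tie-aware)
when both groups have ≤ 10 observations, and the tie-corrected normal
approximation with continuity correction otherwise. P-values are
Holm-adjusted across all pairs (no correction method is canonical here;
Holm is the conservative default of the statistical environments these
analyses are usually run in). Groups with fewer than two observations
are skipped with a warning.

The intensity–length relationship is summarized by OLS with adjusted
R² = 1 − (1 − R²)(n − 1)/(n − 2) and the slope's t-test p-value. Box
plots draw 1.5×IQR whiskers with outlier dots as a rendering convention;
the stored summaries keep the true min/max.

## Benchmarks and problem sizes

The detection benchmark trains on two annotated preset frames and
evaluates five (hours 2–6; 1200×1200 px, 650 cells each, ~3,000
fully-in-frame ground-truth cells total). A ground-truth cell counts as
recovered when exactly one filtered mask component overlaps it with
IoU ≥ 0.5. Cells whose rendered pixels touch the raster border are
excluded from the denominator: the filter cascade removes edge-clipped
particles by design, so including them would measure the protocol, not
the detector. Typical recovery is ~95%; losses are merged neighbors the
classifier failed to separate and small cells eroded below the area or
length bound — the same failure modes reported for comparable detectors.

Regression recovery draws 20 independent populations of 7,000 cells
from the fluorescence model at its defaults and compares the mean
recovered slope/intercept/adjusted-R² to the generative targets within
the estimator's Monte-Carlo dispersion.

## Known limitations

- The length estimator's cap correction assumes hemispherical poles;
  on strongly curved cells shorter than ~3 µm it underestimates by up
  to ~0.5 µm.
- The classifier is only as good as its annotations; the bootstrapped
  synthetic annotations are idealized relative to hand strokes.
- No splitting of merged particles, no multi-layer or 3D scenes, no
  time-lapse tracking, no illumination correction.
- Width defaults in the generator are placeholders (see above), so
  width-distribution results on synthetic data characterize the
  estimator, not any real strain.
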