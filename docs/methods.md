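# Methods

This note records the models, parameter choices and numerical decisions
behind `ovicount`, in the spirit of the methods documentation of mature
scientific Python packages: what is computed, under which assumptions, and
what passing the test suite does and does not demonstrate.

## The assay being modelled

Two female and one male fly are housed in each well of a 48-well plate
(6×8 grid, 300 µL media per well) and transferred to a fresh plate daily.
On measurement days the plate is photographed well by well: a camera moves
in a snake path (row-major, direction alternating per row, starting at the
top-left well), registered to the plate by centering a target on the four
corner wells. Because the rig positions every well identically in its
image, a well boundary found once can be reused for the whole plate. Egg
counts per well are the fecundity readout; dietary chemicals are dosed via
a DMSO serial dilution into the media.

## Plate geometry

Well centers are bilinearly interpolated between the four corner
calibration points using fractional indices `u = col/(n_cols−1)`,
`v = row/(n_rows−1)`. This is exact at the corners, affine-equivariant,
and absorbs plate translation, rotation, scale and mild shear; it does not
model lens distortion (assumed negligible at the rig's working distance).
Coordinates remain floating point in the calibration unit; rounding to
pixel indices happens only when masks are rasterized (round half up). The
traversal's start corner and fast axis are conventions (top-left, rows);
both are fixed here and documented rather than guessed per dataset.

## Synthetic wells

The generator emulates transmitted-light images: bright media background
(grey 180), dark elliptical eggs (grey 45–80), a dark wall annulus (grey
30, 5 px thick) at the well radius, optional additive Gaussian noise
clipped to [0, 255], and optional *reflections* — ellipses rendered exactly
like eggs but placed outside the wall, mimicking mirror images of
wall-adjacent eggs in the clear plastic. Defaults: 600×600 px, 8-bit
grayscale, well radius 260 px.

Egg geometry: analytic area uniform in [2600, 3900] px² with aspect ratio
1.8–2.6, i.e. comfortably inside the 2500–4000 px² filter window so the
printed thresholds are meaningful on fixtures. Placement is rejection
sampling against an occupancy raster; by default instances are strictly
non-overlapping with 2 px clearance. Under that constraint the spec'd
geometry jams near ~16 eggs per well, far below the ~36 eggs/well of a
productive real well, so randomized fixtures default to a mean of 12 eggs
per well; the plate renderer accepts any per-well spec list and records
the *actually placed* eggs as truth if a requested density saturates.

What the generator does **not** model: yeast texture, larvae or adult
flies in frame, focus variation, illumination gradients beyond noise, and
partial or distorted reflections. Passing counts on these fixtures
demonstrates the pipeline's contracts (filtering, masking, NMS, matching,
statistics) — it does not certify real-image accuracy, which depends on a
trained segmentation model supplied through the backend registry.

## Preprocessing and well detection

Preprocessing averages color channels, inverts (eggs become bright), and
linearly maps the 1st/99th intensity percentiles to 0/255 with clipping —
robust to hot pixels where min–max stretching is not. Normalization is
per-image; a constant image degenerates to mid-grey 128 with a warning.
Re-normalizing an already-normalized image moves no pixel by more than one
grey level.

The boundary is found on a Canny edge map (Gaussian σ 2, hysteresis at the
70th/90th gradient-magnitude quantiles) with a seeded RANSAC circle fit
(500 trials, 3 px inlier tolerance) constrained to ±15% of the supplied
diameter estimate. The rendered (and real) wall has finite thickness, so
the edge map holds an inner and an outer ring; since the counting mask
must follow the *inner* wall edge, the consensus fit is iteratively
re-fit on the innermost edge band (10th-percentile radius ± 2 px, three
rounds). `fit_quality` is the fraction of 180 angular bins around the
fitted circle containing an edge pixel within tolerance — a coverage
measure chosen over the raw inlier fraction because egg edges legitimately
dominate the edge map of a productive well. Quality below 0.5 raises a
detection error carrying the fallback boundary (image center, radius =
estimate/2). An ellipse model is available behind a flag; the circle is
the default (fewer parameters, wells are circular). The counting mask is
eroded 2 px to exclude wall pixels.

## Reference egg detector

The production segmenter for this assay is a trained star-convex deep
model whose weights are external to this package; any such model can be
registered as a backend. The built-in *reference detector* is a fully
deterministic pipeline implementing the same contracts:

1. Gaussian smoothing (σ 2) and Otsu thresholding (mean-threshold
   available) of the preprocessed image.
2. Connected components; components below 400 px² are discarded (noise
   specks and wall-edge slivers — well below any egg, which is ≥ 2500 px²).
3. Fused-egg splitting: every component is probed with a Euclidean
   distance transform. A single convex egg has a unimodal distance ridge;
   a fused pair has one interior maximum per egg. Peaks closer than the
   component's own maximum thickness are merged, and when ≥ 2 peaks
   remain the component is split by one marker-based watershed step
   (splits producing a fragment under 400 px² are rejected). An earlier
   design split only components above a multiple of the median candidate
   area; it was abandoned because the fused components themselves inflate
   the median exactly when splitting is most needed.
4. Star-convex polygon: `n_rays` (default 32) rays cast from the
   intensity-weighted centroid, sampled at 0.5 px steps; each vertex is
   the last in-component point plus half a pixel (boundary pixels extend
   past their centers — without this offset the rasterized polygon
   under-covers the component by ~3–5%, enough to push small eggs below
   the 2500 px² filter bound). The instance mask and area come from
   rasterizing this polygon, so instances are star-convex by construction.
5. Score = geometric mean of (a) Michelson foreground/surround contrast
   of medians over a 5 px ring (medians keep a bright neighbour or the
   wall from depressing the score) and (b) an ellipse-residual score
   `1 − 4·rms(ρ−1)` where ρ is each vertex's normalized elliptical radius
   in the least-squares-fitted ellipse frame. Both live in [0, 1]; clean
   eggs score ≈ 0.8–0.95, irregular debris lower. This score is the
   reference backend's analogue of a learned model's probability — the
   0.7 default threshold and 0.3 NMS IoU ceiling are shared conventions,
   and the tuned production preset 0.706 is exported as a constant.

NMS is greedy by descending score with fully specified tie-breaks (larger
area, then centroid raster order) so runs are bit-reproducible. The
threshold is applied before NMS. The area filter is applied after NMS, on
the rasterized mask, before any morphological cleanup. The inside-well
rule is centroid-inside (an egg touching the wall counts once);
full-mask-inside is available.

## Evaluation

Instance matching maximizes the number of prediction–truth pairs with
IoU ≥ τ via the Hungarian algorithm on the thresholded IoU matrix (a small
IoU bonus breaks cardinality ties toward better overlap); greedy matching
is available behind a flag. Metrics follow the star-convex segmentation
convention: precision = tp/(tp+fp), recall = tp/(tp+fn), and accuracy
(average precision at τ) = tp/(tp+fp+fn), reported to 4 decimals, with
0/0 ratios reported as 1 and flagged degenerate. Count agreement is the
R² of an OLS fit *with intercept* of automated on manual counts (scatter
fits, not forced through the origin).

## Fecundity statistics

**Inclusion.** A condition-day is excluded entirely unless wells with both
females alive number at least ⌈n/2⌉; in retained groups exactly the
both-alive wells are kept. The rule is idempotent and only ever removes
wells.

**Summaries.** Mean, sample SD (ddof 1) and CV = SD/mean per
condition-day; CV is flagged undefined at mean 0.

**Tests.** Two-sample t-tests, Welch by default (the pooled-variance test
is a flag) — the unequal-variance default is the safer choice when dosed
conditions shrink both mean and variance of counts. The Bonferroni family
is the set of comparisons requested in one call: adjusted p = min(1, m·p).
Significance stars at 0.05/0.01/0.001 on adjusted p.

**Synthetic counts.** Negative binomial with mean µ and dispersion θ
(variance µ + µ²/θ). Defaults µ = 36, θ = 2.7, reproducing the observed
day-1 behaviour of the real assay (≈ 36 eggs/well, interwell CV ≈ 0.63);
Poisson is available but real counts are strongly overdispersed. Survival
is Bernoulli per female with per-day probability pᵈ.

**Downsampling power.** Each iteration draws k wells without replacement
independently from each condition and re-runs the t-test; the fraction of
iterations with p < α estimates the power at k replicates. One seed
drives the whole run. A subtlety worth knowing: with a fixed pool of
wells, the fraction converges (in iterations) to the rejection rate
*conditional on that pool*, whose expectation over pools is the nominal
rate but whose spread is governed by pool-level sampling noise, not by
the iteration count — under the null with 60-well pools and k = 16 the
conditional rate typically lands between 0.02 and 0.07 around a mean of
≈ 0.045. The acceptance script therefore averages the null calibration
over ten independent pools.

## Dosing

The serial dilution reports each step's fold-concentration and DMSO
percentage under the bench convention that 30 µL into a 300 µL well is a
10-fold step (1000× stock in 100% DMSO → 1:100 → 10× in 1% DMSO → nominal
1× in 0.1% DMSO), and alongside it the exact volumetric value
(30/330 = 10/11 of nominal), labelled "exact" — the two are never silently
mixed. Intake is `conc (µM) × MW (g/mol) × consumption (µL/day) × 10⁻³`
ng/day, with display rounding of 2 decimals below 1 ng and 1 decimal
above, and a built-in convenience table (rapamycin 914.17, bendiocarb
223.23 g/mol) that user-supplied weights override. At 25 µM bendiocarb
this arithmetic gives 8.37 ng/day; the commonly quoted 8.3 presumably
reflects a different rounding or molecular-weight source, so that single
value is documented rather than asserted. Pharmacokinetics and cuticular
absorption are out of scope.

## Problem sizes and determinism

The test suite and acceptance script run the image pipeline on 120–200
synthetic wells (≈ 0.4 s per 600×600 well on one CPU), the matching
oracle on instance sets of ≤ 6 (where exhaustive assignment is feasible),
and the power analysis at 200–2000 iterations — sizes chosen so the whole
suite completes in a few minutes while keeping every estimate's Monte
Carlo error well inside the asserted bounds. Every random quantity flows
from an explicit integer seed (numpy `default_rng`); identical seeds give
byte-identical images, CSVs and p-value vectors.

## Known limitations

- The reference detector's score is hand-crafted; its absolute values are
  calibrated on synthetic contrast and do not transfer to real images.
- Touching-egg splitting assumes approximately convex instances; chains
  of three or more mutually touching eggs at odd angles can under-split.
- The circle model under-fits visibly elliptical wells (tilted camera);
  use the ellipse flag there.
- The inclusion rule needs explicit survival records; wells missing them
  are a hard error by design rather than silently assumed alive.
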