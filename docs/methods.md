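# Methods

## Problem and model

A fibrous scaffold seeded with cells is imaged as a z-stack of the nuclear
stain: `n_layers` single-channel frames separated by `layer_spacing_um`
(default 14 layers at 7 µm, matching a typical confocal scan of an
electrospun mat). A nucleus physically sits at one depth but is optically
visible in several frames; the pipeline's unit of inference is therefore
the *nucleus record*: one physical nucleus, one assigned layer. All
downstream kinetics consume only the per-layer counts `C_z` and the total
`C_summ`.

Depth is measured from the seeding surface (layer 0 = first scanned
layer). Conversion curves use layer midpoints, `z_i = (i + 0.5) * dz`, so
`alpha(z_i)` is the fraction of cells within the first `i+1` layers; the
nucleus table's `depth_um` column follows the layer-top convention
`assigned_layer * dz`. Both conventions are stated here because figures
built from the two tables would otherwise disagree by half a layer.

## Synthetic stacks

The generator emulates what the assignment problem actually needs and no
more:

* Nuclei are 2-D ellipses (full axes drawn from 8–14 µm × 5–9 µm) rendered
  into every layer, not true 3-D ellipsoids. Lateral placement enforces
  non-overlap (clearance = sum of semi-major axes + 2 px).
* Defocus: Gaussian blur of scale `sigma = blur_growth * |dz_layers|`
  (default 1 px per layer) on top of a 0.7 px in-focus PSF, with intensity
  attenuation `1/(1 + sigma^2)`. With these defaults a nucleus is
  detectable roughly ±2 layers around its focal plane, which is what makes
  deduplication non-trivial.
* Additive Gaussian noise, default `noise_sd = 0.02` on a [0, 1] intensity
  scale with 0.03 background. The focus-localisation property (sharpness
  maximal at the true layer) holds comfortably up to `noise_sd ≈ 0.05`;
  beyond that, segmentation rather than focus scoring fails first.
* Depth placement follows one of three regimes — `surface`
  (`1 - exp(-kz)`), `exponential` (delayed variant) and `hill`
  (`z^n/(K^n+z^n)`, defaults n = 3, K = 40 µm) — so kinetics fitting has
  in-distribution data. The model CDF is evaluated at layer midpoints and
  the tail mass beyond the deepest midpoint is absorbed by the last layer;
  this keeps the cumulative fraction at layer i exactly equal to the CDF
  at `z_i` (a normalised CDF would bias the Hill midpoint property).

What the generator does *not* emulate: scaffold-fibre background texture,
photobleaching, anisotropic PSFs, lateral drift between layers, nucleus
shape irregularity. Passing tests demonstrate the pipeline's correctness
under controlled optics, not robustness to every real-microscope artefact.

## Segmentation

Classical path (default and reference): Gaussian smoothing (1 px) →
threshold → hole filling → optional watershed split → area filter
(30–8000 px). Otsu thresholding is floored at a robust background ceiling
(median + 4·1.4826·MAD) because Otsu always bisects a histogram, even of
pure noise; the floor keeps empty layers empty. For whole stacks the Otsu
threshold is pooled across layers (`threshold_scope="stack"`): a layer
containing only defocused haze gets the threshold set by the layers that
contain real signal.

Watershed markers are peaks of the smoothed distance transform with a
7 px minimum separation (about one nucleus radius at the default
calibration); smoothing the distance map suppresses twin peaks inside one
elongated nucleus.

Frames larger than `tile_size_px` (default 1024) are thresholded per tile
with a 64 px overlap; each tile contributes only its core (half the
overlap trimmed at interior edges), so smoothing edge effects never reach
the stitched result and tiled output equals whole-image output exactly for
fixed thresholds. Filling/splitting/filtering then run globally, so
objects crossing tile borders stay whole.

Overlap metrics: `iou = |A∩B|/|A∪B|`, `dice = 2|A∩B|/(|A|+|B|)`; both
defined as 1 when both masks are empty (nothing to find, nothing found).

## Deduplication and layer assignment

Detections in consecutive layers are candidate matches when centroids are
within `max_centroid_shift_px` and patch SSIM ≥ `ssim_threshold` (0.5).
Patches are bounding-box crops (+4 px margin) resized to a common window;
SSIM uses the standard constants with a 7 px window. Matching per layer
pair is an optimal one-to-one assignment maximising total SSIM
(Hungarian algorithm), which is deterministic and — for adjacent-only
links — globally optimal over all consistent groupings, a property the
test suite verifies against brute-force enumeration. A second assignment
pass lets chains bridge `max_layer_gap = 1` missed layer.

The matching radius defaults to 6 px ≈ half a typical nucleus major axis.
The centroid of one nucleus drifts only a pixel or two between focal
planes (segmentation jitter of the blurred outline), while a radius of a
full major axis would admit a touching neighbour as a candidate and let a
chance higher SSIM capture the chain, double-counting the abandoned
nucleus. Half an axis absorbs the real jitter and excludes neighbours by
construction.

Each chain becomes one record assigned to its sharpest member — variance
of Laplacian by default, Tenengrad as the alternative — with ties broken
toward the smaller layer index.

## Kinetics

`alpha(z)` is the cumulative count fraction (the per-layer fraction
`C_z/C_summ` is reported alongside; the two are easily conflated).
Model fitting is bounded least squares (`scipy.curve_fit`), initial
guesses K = median z, n = 2, rate k = 1/median z; non-convergence returns
`converged=False` with a message, never a silent answer. Best-of-three
selection scores fits by AIC rather than raw residual because
`depth_exponential` nests `surface_exponential`; without the parameter
penalty the simpler model could never be selected.

`z(alpha)` inverts the conversion curve by monotone piecewise-linear
interpolation anchored at (0, 0); an alpha value spanned by a flat
segment resolves to the segment midpoint and is flagged. Activity is
evaluated at the nine 10% increments 0.1–0.9 and summarised by the slope
of an ordinary least-squares line through all nine points (configurable
via `alpha_steps`). The proliferation rate for an interval is `C_summ` at
the interval's end divided by the interval length in days (default
intervals 1, 3, 3 days — seeding→day 1→day 4→day 7); interval-average
counts can be substituted by passing the profiles explicitly. The activity
share up to a cell fraction is the trapezoidal area fraction of the
activity curve.

## Morphometrics

Shapes come from second image moments (ellipse of equal moments); the
minor axis is floored at one pixel with a `degenerate` flag for 1-px-wide
objects. Axis ratio is major/minor ≥ 1. Log-normal fits are
maximum-likelihood on log-values with a Kolmogorov–Smirnov distance as
the goodness-of-fit statistic. Group comparisons: Tukey HSD on means for
independent groups; for matched repeated measures, a Friedman omnibus
test gated over pairwise Wilcoxon signed-rank tests with Holm adjustment
(the pairwise flags require the omnibus to pass). Significance level 0.05
throughout.

## Trainable segmenter

A one-level encoder–decoder of the U-Net family written directly in
NumPy: 3×3 conv (8 channels) → mean-pool ×2 → 3×3 conv (16) → nearest
upsample + skip concatenation → 3×3 conv (8) → 1×1 conv → sigmoid. Loss
is 0.5·BCE + 0.5·soft-dice; optimisation is Adam (lr 5e-3) with
per-image updates. A held-out validation split is mandatory and training
and validation IOU are recorded per epoch; gradients are verified against
finite differences in the test suite. With `deterministic=True` data
order and initialisation are fixed by the seed, so runs are bit
reproducible. The classical path remains the default segmenter; the model
is a drop-in honouring the same `LayerMask` contract.

## Problem sizes and numerical choices

Test and reproduction runs use 14-layer stacks of up to 1024² px with 200
nuclei, 100-replicate kinetic recoveries, and 200 training pairs of 128²
px — sizes chosen so the whole suite completes in a few minutes on one
CPU while every stage still operates in its intended regime. Tie-breaks
are documented where they exist (focus ties → smaller layer; assignment
via deterministic Hungarian solve); empty inputs are contracts, not
errors (empty stack → zero-count profile, kinetics skipped with a logged
reason; empty mask pair → IOU 1).

## Known limitations

* The defocus model is isotropic and symmetric in z; real confocal PSFs
  are neither. Focus assignment may degrade on strongly asymmetric optics.
* Deduplication assumes nuclei do not move laterally between layer
  acquisitions (fixed samples); it is not a tracker for time-lapse data.
* `depth_exponential` and `surface_exponential` are two reasonable
  readings of "settling" vs "infiltrating" exponential regimes; other
  parameterisations fit the same data comparably.
* The trainable segmenter is deliberately small (CPU-scale); it is not a
  replacement for a full-scale trained network on real micrographs.
* CZI input is out of scope; convert proprietary stacks to OME-TIFF or
  PNG layers first.
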