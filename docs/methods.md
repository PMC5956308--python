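# Methods

This note records the measurement models, the phantom's generative model,
the numerical choices and their rationale, and what the validation suite
does and does not demonstrate.

## Coordinate and unit conventions

Images use 0-based pixel indices, x rightward, y downward.  All phantom
geometry is generated and stored in micrometres; pixels enter only at
render time through `pixel_scale_um` (so regenerating at a different pixel
scale leaves the µm-unit ground truth bit-identical).  Orientations are
tangent directions modulo π — a vessel axis has no preferred sign — and all
circular statistics double the angles before averaging, the standard
embedding for axial data.  Velocity conversion is pinned as
px/frame × (µm/px) × (frames/s) / 1000 = mm/s.

## Software phantom

A nailfold is a left-to-right row of hairpin loops.  Each loop is built by
integrating a heading function along arc length at 1 µm steps: a straight
arterial limb (default 100 µm, the distance over which paths are measured),
a semicircular apex turn, and a straight venous limb.  Tortuosity is
Gaussian white noise smoothed to a ~12 µm correlation length, scaled to a
target SD (radians) and added to the heading before integration, so paths
wobble smoothly and remain traceable.  Principal orientations are
wrapped-normal about vertical with SD `derangement_spread`.  Apices are
spaced by a jittered mean spacing; loops whose rotation would carry them
outside the canvas are relaxed toward vertical until they fit.

Photometric model: vessels are dark tubes on a constant bright background
(200) with a Gaussian cross-section; **width is defined as the full width of
the profile at half its depth** (FWHM), the same definition the width
estimator uses, so width ground truth is unambiguous.  The apex turn
diameter is 2.5 × the local width: a turn of diameter equal to the width
would place the two limbs' profiles (each FWHM = width) right on top of one
another, with no intensity dip between them — the loop would render as one
blob and neither the width nor the apex ground truth would be meaningful.

Video frames add advecting "cells": dark elliptical Gaussian blobs at
Poisson-spaced arc-length positions (mean gap 25 µm — plasma gaps), moved
along the centerline by `velocity × 1000 / frame_rate` µm per frame with
wrap-around, over static vessel walls drawn at weaker contrast (25 vs 60)
so the temporal signal dominates along the lumen.  The blob's cross-path
FWHM equals the capillary width: what capillaroscopy images is the moving
red-cell column, and the temporal mean of the video — which is what the
width estimator sees after mosaicking — must agree with the width ground
truth.  Its along-path FWHM is 8 µm (a red-cell-sized packet).

Defaults are anchored to healthy-control population values: width 11.8 µm,
cell speed 0.311 mm/s, apex spacing 150 µm (≈ 6.7 apices/mm), derangement
spread 0.45 rad (wrapped-normal R = e^(−2σ²) ≈ 0.67).  Group presets for
HC/PRP/SSc move width, spacing, speed, tortuosity and derangement to the
corresponding group means, with between-subject SDs derived from the
population standard errors.  Acquisition defaults match the imaging
hardware: 640 × 480 px, 1 µm/px, 120 frames/s.  Default noise SD 4 gives a
tube-contrast SNR of 15; validation runs also use SNR 10 (noise 6).

What the phantom does **not** emulate: illumination gradients and
vignetting, skin autofluorescence and texture, haemorrhages and avascular
areas, giant-capillary morphology beyond width scaling, out-of-plane loop
geometry, pulsatile or reversing flow, and motion blur.  Passing the
validation suite therefore demonstrates the correctness and calibration of
the algorithms under the stated image model, not clinical performance.

## Mosaicking

Translation-only registration (the motorised stage moves in-plane; there is
no evidence of rotation).  Consecutive frames are registered by normalised
cross-correlation of the overlap region inside a ±20 px search window
around the nominal stage offset; the integer peak is refined by upsampled
phase correlation of the aligned overlap patches, with a 1-D parabolic fit
as fallback.  Frames are presmoothed (Gaussian σ = 1.5 px) for registration
only: vessels carry no structure below that scale, and the smoothing
suppresses the sensor noise that otherwise jitters the correlation peak
along the nearly-y-uniform vessel axes.  Offsets within 0.1 px of an
integer are snapped (below registration precision).  Pairs that fail or
score under 0.3 fall back to the nominal offset and raise a quality flag.
Overlapping pixels are composited by per-pixel mean, which simultaneously
denoises the static scene; with sub-pixel offsets frames are placed
bilinearly with matching weights.  On phantom tiles with ≤ 10 px nominal
jitter the refined offsets land within ~0.1 px of truth.

## Detection and morphometry

**Ridge filter.**  Gaussian-derivative Hessian at scales matched to target
widths (σ = width / 2.355 / pixel scale, default widths 8–25 µm), response
= σ² · max(λ₁, 0) where λ₁ is the most positive eigenvalue (dark tube ⇒
large positive second derivative across the vessel), maximised over scales.
The vessel orientation is perpendicular to λ₁'s eigenvector, computed from
whichever of the two analytic eigenvector forms is better conditioned at
each pixel.  A border band of 3σ_max is blanked (derivative edge
artefacts).

**Apex detection.**  Apices are turning points of the orientation field:
the response-weighted axial coherence (smoothed mean resultant length of
doubled orientations, σ = 8 µm) collapses where both limbs and the turn
mix, so candidates are local maxima of response × (1 − coherence) above an
absolute response threshold, non-maximum-suppressed at 30 µm.  Each
candidate is refined within a window: the strong-response connected
component is taken, the apex is the component's extreme pixel along the
loop's own principal axis (window-edge pixels excluded, so a neighbour's
limb clipping the window cannot pose as the turning point), slid down that
axis onto the response crest.  The refined point is verified by geometry:
at a true turning point the local tangent runs perpendicular to the loop
axis, whereas on a limb or at a vessel-end termination it runs along it, so
candidates whose tangent lies within 30° of the axis are rejected (the
threshold tolerates axis estimates blended with neighbouring loops while
still rejecting terminations).  A distal-row band keeps only apices within
80 µm of the topmost detection.  Merging keeps the higher score; ties the
leftmost; output is sorted left-to-right.

**Tracing.**  Bidirectional steepest-ridge following from the apex at 1 µm
arc steps, re-centering each step on the transverse response crest over a
window matched to the locally detected scale; a step is rejected (branch
terminated) when the transverse profile loses prominence (< 1.15 × the
window edge), which stops traces from walking into the smooth blur beyond
vessel ends.  Limbs truncate at 100 µm arc length or when the response
falls below 25 % of the apex response.

**Widths.**  At each path point the intensity is sampled with cubic-spline
interpolation along the normal (±30 µm, 0.25 µm steps, 0.5 µm profile
smoothing); width = full width at half the profile depth, with the
background taken as the median of the top quartile and the minimum searched
within the central ±35 % (so neighbouring vessels do not capture it).
Cubic sampling matters: bilinear interpolation alone widens an 8 µm profile
by ~3–4 %.  Points whose profile leaves the image or shows depth < 8
intensity units are flagged and excluded; a capillary with > 50 % flagged
points raises an error and is dropped with a warning.

**Summaries.**  Per capillary: mean width over measurable points; principal
orientation = axial circular mean (half the argument of the mean
doubled-angle vector — an arithmetic mean of raw angles is ill-defined
mod π); shape score = dispersion R of path orientations.  Per nailfold:
density = n_apices / span where span is the leftmost-to-rightmost apex
distance ("apices per millimetre" read literally as n/span, not
(n−1)/span); mean/max width; mean shape score; derangement = R of principal
orientations; mean flow over capillaries with a valid velocity.  Per
subject: unweighted mean per parameter over the digits where it is defined,
so a digit with a failed flow measurement still contributes its structural
parameters (mirroring cohorts in which some digits cannot be imaged).
Fewer than two capillaries leave density undefined (NaN) for that digit
only.

## Velocimetry

Dense iterative Lucas–Kanade flow, written in-house: Gaussian-derivative
spatial gradients, 15 px uniform aggregation windows, eight Gauss–Newton
warp iterations (per-iteration step clipped to 2 px), validity by
structure-tensor conditioning.  Cell speeds of 0.1–0.5 mm/s at 1 µm/px and
120 fps are 0.8–4.2 px/frame, within the iterative scheme's range.

Two estimator details matter and are deliberate:

* **Temporal-energy weighting.**  The window equations weight each pixel by
  its windowed squared temporal difference minus the noise baseline (the
  median over the crop — almost all of which is static scene).  Without it,
  static wall gradients inside every window drag the estimate toward zero
  (≈ −20 % bias); subtracting a static background image instead corrupts
  the slow-flow and zero-flow cases.
* **Per-limb signed averaging.**  Flow vectors sampled at path points are
  projected on the local tangent; the projection is averaged *signed*
  within each limb (flow direction is coherent along a limb), then the
  absolute per-limb means are combined weighted by point count.  Averaging
  |projection| point-by-point instead rectifies noise and floors the
  static-scene estimate well above zero.  Speed, not signed velocity, is
  reported, because the arterial/venous sign convention is not observable.

A frame pair reports speed 0 when the mean windowed temporal energy over
the path region is below 1.05 × the global median: for truly static scenes
this ratio stays ≤ ~1.03, while 0.1 mm/s flow lifts it to ≥ ~1.14, so the
gate pins the static noise floor at 0 at the cost of a detection limit of
roughly 0.05 mm/s.  About 15 path points at the outer end of each limb are
excluded: a cell leaving the measured segment at one limb end (and, in the
phantom's wrap-around steady state, re-entering at the other) produces
gross non-translational correspondences localised there.  The capillary's
velocity is the mean of per-pair speeds over all consecutive frame pairs in
which the apex is visible (inside the frame with a 20 px margin); a
flag-gated 10 % trimmed mean is available.  Recovered means are within
~8 % of truth across 0.1–0.5 mm/s; per-seed scatter at 10 frames is
~10–25 % at the slowest speed.

## Cohort statistics

ANOVA uses the textbook between/within decomposition (degenerate inputs:
all-equal values give F = 0; zero within-group variance with differing
means gives F = ∞); Tukey's range test uses SciPy's Tukey–Kramer
implementation, correct for the unequal group sizes typical here.  ROC
areas use the rank (Mann–Whitney) formulation with half-credit ties, the
Hanley–McNeil standard error, and auto-orientation for single parameters
(recorded in the output); cross-validated probabilities are never
auto-oriented, since their direction is part of the estimate.

The combined classifier is bidirectional stepwise logistic regression,
started from the full main-effects model, with SSc as the positive class
and HC/PRP pooled as the negative class.  The selection criterion is
**BIC** rather than AIC: at n ≈ 100, AIC's per-term penalty of 2 admits a
pure-noise parameter in roughly one LOOCV fold in six, and folds that
overfit noise anti-predict their held-out subject, dragging the null
cross-validated A_Z median to ≈ 0.43; with BIC the null median is 0.50 with
all seeds in [0.35, 0.65].  `criterion="aic"` remains available.  Inputs
are z-scored internally; coefficients are reported on the original scale.
Quasi-separation triggers a unit-ridge refit flagged `penalized`.  Logistic
fits use a compact Newton solver with step-halving (LOOCV with nested
selection needs ~10⁵ small fits; statsmodels is the cross-check oracle in
the tests, not the engine).

LOOCV re-runs the entire selection + fit on each fold.  A fold that selects
no terms emits the uninformative score 0.5: scoring by the training
prevalence would leak the held-out label (the prevalence is lower exactly
when the held-out subject is positive) and drives the null A_Z to 0 as a
pure artefact.  The cohort report computes, deterministically and
row-order-invariantly: group means ± SE with pairwise significance flags,
per-parameter A_Z ± SE, and the combined structure-only (five structural
parameters) and structure + flow models; cohorts below 10 subjects fall
back from LOOCV to a resubstitution ROC, flagged in the output.

## Problem sizes in the validation suite

The suite and `scripts/acceptance.py` use reduced problem sizes chosen to
exercise every code path at full fidelity: oracle checks at 1000/500 random
instances; 20-seed mosaic and detection sweeps (3 tiles of 300 × 420 px;
4–12 capillaries per mosaic); 10 seeds per velocity operating point with
10-frame, 300 × 240 px videos; 50 null cohorts of n = 100 for classifier
calibration; and a 6-subject end-to-end cohort at 260 × 460 px.  The full
suite runs in under two minutes on one core.

## Known limitations

Width estimates carry a small positive bias (≈ 2–7 %, largest for the
narrowest vessels) from discretisation and the apex turn region; apex
localisation is good to a few µm, degrading for strongly rotated loops;
velocity has a ~0.05 mm/s detection limit and mild (≲ 8 %) underestimation
from residual static-gradient dilution; registration assumes pure
translation; and the distal-row rule (a band below the topmost apex)
presumes a roughly horizontal row, as in the phantom and in typical
nailfold mosaics.
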