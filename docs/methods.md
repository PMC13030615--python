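# Methods

This note documents the models behind each stage, the parameters that
matter, the synthetic-data generator's scope, and the numerical choices
made where the design was genuinely open.

## Coordinate conventions

World frame: x downhill, y across the slope, z up, metres. Image frame:
origin top-left, x right, y down, pixels. Camera `c`'s integer frame `f`
is exposed at absolute time `(f + δ_c) / fps`, where `δ_c` is that
camera's fractional frame offset; synchronization estimates `δ_c − δ_ref`
and resamples every stream onto the reference camera's grid.

## Synchronization model

The dropped cube's height is `h(t) = h₀ − g(t−t₀)²/2` during free fall and
a restitution-scaled parabola after impact; with a horizontal optical axis
the vertical pixel coordinate is an affine image of height, so each phase
is an exact parabola in time. Phase segmentation works on first and second
differences of the trace:

* the impact is the first downward-to-upward velocity reversal whose
  magnitude exceeds 25 % of the peak fall speed — scaling the threshold
  with the trace itself means rest-phase jitter can never fake a reversal
  while a genuine impact (near-peak speed on both sides) always clears it;
* the leading rest phase is trimmed with a threshold of
  `max(1.5 px, 0.1 × peak fall speed)`; the first clearly-moving sample's
  predecessor straddles the release instant and is skipped;
* the sample at the reversal apex may lie on either side of the impact and
  joins neither window.

Each window (≥ 3 samples) is fitted by least-squares quadratic; the event
is the intersection root inside the inter-window gap (with two admissible
roots, the one nearer the gap midpoint). On noise-free synthetic drops the
event is exact to ~1e-9 frames; with 1 px trace noise the measured mean
absolute offset error is below 0.01 frames, comfortably under the 0.05
frames at which a 15 m/s skier would move 3 mm.

Resampling is linear interpolation between neighbouring frames, producing
a value only where both neighbours exist and carry the same identity;
confidences take the neighbour minimum. Linear interpolation is exact for
constant-velocity motion and leaves a curvature-dependent error
`a Δt²/8` otherwise (≈ 3 mm at 13 m/s² lateral acceleration and 25 fps) —
one reason the "noise-free" acceptance scenario also injects zero offsets.

## Reference-point association

Overlap filtering uses IoU with a strict `> 0.5` cut and removes *both*
members of an overlapping pair: when two cube boxes overlap that much,
assigning either identity is a guess. Identity matching requires the
decoded marker centroid to fall inside a box (nearest box centroid on
ties; a box containing two distinct identities is discarded as a
conflict). The inter-frame shift is the component-wise *median* of
centroid displacements over common identities, robust to one mis-tracked
cube. Temporal recovery projects the previous frame's identified
centroids by that shift and greedily matches them, nearest first and
one-to-one, to still-unknown boxes within a radius.

The default radius is the projected box diagonal. A translation-only
shift vector cannot absorb the radial image motion that zooming induces
(≈ 1 % of off-centre distance per frame in the simulated scenes), and a
half-diagonal radius was measured to miss roughly a third of eligible
recoveries; the full diagonal recovers ≥ 98 % of them while remaining far
below the inter-cube image spacing, so mis-assignments were never
observed. The radius is a parameter for scenes with different optics.
Recovered detections carry `provenance="recovered"` so calibration could
down-weight them (default: equal weight). Recovery is bounded by identity
availability: a cube that enters the view unidentified and has never been
seen cannot be recovered by any temporal scheme, so recovery rates are
reported against eligible drops (identified in the previous frame).

## Calibration

The DLT stacks two homogeneous equations per correspondence and takes the
SVD null-space vector, with isotropic (Hartley-style) normalization of
both point sets before solving. The result is scaled to unit Frobenius
norm with the sign fixed by positive median projective depth. Degeneracy
is detected as a second vanishing singular value of the normalized design
matrix (`s₁₁ < 1e-8 · s₀`): a coplanar point set determines `P` only up to
a family, and the literal "relative gap between the two smallest singular
values" is numerically meaningless when both are round-off zeros.

Outlier rejection removes one worst-reprojecting point per iteration and
keeps the removal only if the mean reprojection error of the remaining
set drops by ≥ 5 % (relative). Two stopping guards: a floor of six points,
and a numerical floor of 1e-9 px mean error below which the relative rule
would compare round-off values. The per-frame point budget is the 15
identified cubes nearest the skier's image centroid (the projected true
centroid in synthetic trials; a person-box centre in real use), because
calibration accuracy matters most where the skier is.

## Reconstruction

Triangulation uses the same two-rows-per-view system, rows normalized to
unit norm, solved by SVD; points with a vanishing second-smallest singular
value (near-parallel rays) or vanishing homogeneous scale are flagged
unstable and dropped. Subset selection exhaustively scores every camera
subset of size ≥ 2 (capped at 8 cameras, 247 subsets) by the mean
reprojection error into the subset's own views, with ties — within
1e-6 px, to absorb round-off on noise-free data — broken toward the larger
subset, then lexicographically. Note the self-consistency score is
optimistic for two-view subsets (two rays almost always intersect); the
biased-camera exclusion this search is meant to provide still holds, and
a fixed evaluation subset can be forced via configuration.

Smoothing is a 4th-order Butterworth applied forward-backward (zero
phase, squared magnitude response), cut off at 10 Hz for 25 fps data —
standard kinematics practice. Interior gaps of ≤ 5 frames are bridged by
linear interpolation for the filter pass and re-masked afterwards; longer
gaps split the series into independently filtered runs; runs too short
for stable zero-phase filtering are passed through unfiltered.

## Evaluation

Segment-length variation uses the sample (n−1) SD of per-frame Euclidean
lengths of the eight arm/leg segments, with the overall score the
arithmetic mean of per-segment SDs; a segment needs two valid frames to
report. PCK counts a keypoint correct within `0.05 × max(bbox side)` of
truth, where the box is spanned by visible truth keypoints; mAP averages
over OKS thresholds 0.50:0.05:0.95 the fraction of instances clearing
each threshold, with standard person-keypoint sigmas (ski and pole
endpoints take the ankle sigma); MPJPE is the mean pixel error over
keypoints visible in both sets. Cross-run comparisons use t-based 95 %
CIs of run-wise means and two-sided Wilcoxon signed-rank tests on paired
run values, discarding zero differences (all-zero pairs report p = 1).

## The synthetic scene generator

The generator emulates, at reduced scale, a field protocol of ~300
surveyed cubes in a 250×80×30 m corridor watched by up to eight 4K
camcorders. Defaults (all configurable): 60×20×10 m corridor at 15°
slope, 4 cameras at 28 m lateral stand-off, 80 cubes on 0.5–1.5 m poles
scattered clear of the skier's line (varying heights keep the field
non-coplanar), 25 fps, 3840×2160 images, 100 frames. The skier descends
at 15 m/s (typical carving speed) with 3 m sinusoidal turns at a 3 s
cadence; all eight measured segments are built as
`parent + length · unit(direction)`, so their ground-truth lengths are
constant to machine precision. Cameras aim at the skier centroid
(optional operator lag) and zoom linearly with distance to hold
~200 px/m at the skier; the pinhole model has no distortion, mirroring
optics operated in a mid/far zoom range where distortion is negligible.
Observation models: Gaussian centroid noise (default 0.5 px), detection
dropout (0.05), identification dropout (0.10), Gaussian keypoint noise
(2 px), per-camera fractional frame offsets, and post-survey cube drift
up to a configurable magnitude (0 by default; 0.16 m is the largest
shift the field protocol reported). Every draw comes from one seeded
generator, so identical configs are bit-identical.

What the generator does *not* model: photorealistic appearance, geometric
occlusion (dropout is random, not ray-cast), rolling shutter, lens
distortion, snow spray, or detector confidence structure (confidences are
drawn uniform). Passing tests therefore certify the geometry, association
and statistics of the pipeline — not the neural detectors, which are
outside the package's scope and enter only as detection-stream inputs.

The 2×2 manual/automatic experiment renders one noise-free scene per
seed and emulates annotation quality by noise magnitude: 1 px (automatic)
vs 4 px (manual) on cube centroids, 2 px vs 5 px on keypoints — the
4 px manual figure matching the scale of manual-vs-automatic cube
disagreement reported in the field, with automation the lower-noise
channel in both factors. The claim tested is the *ordering* of overall
segment-length SD, averaged over ≥ 20 seeds; printed field magnitudes
depend on unreleased recordings and are deliberately not targets.

## Problem sizes

Simulated trials in the test and acceptance suites use 30–100 frames,
2–4 cameras and 50–80 cubes; Monte-Carlo loops use 50 seeds (sync), 100
cameras (DLT), 1000 points (triangulation) and 10–20 seeds (factor
experiment). These sizes give the assertions comfortable statistical
margin while keeping a full run to a couple of minutes on one CPU.

## Known limitations

* Linear resampling caps accuracy for strongly curved motion at low frame
  rates; a spline or constant-acceleration model would lift it.
* The subset-selection score favours small subsets under noise (see
  above); reprojection into *held-out* views would remove the bias at the
  cost of per-frame error comparability with the in-view score.
* Confidence weighting of triangulation rows is implemented but off by
  default, as the upstream weighting scheme is detector-specific.
* The simulator's dropout is independent per observation; correlated
  occlusion (e.g. the skier blocking a whole sight-line for many frames)
  would stress temporal recovery harder than the tests do.
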