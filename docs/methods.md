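# Methods

`fimflow` implements the image-processing chain of an autonomous
flow-imaging microscope used for freshwater phytoplankton monitoring:
widefield frames are segmented into particle regions of interest (ROIs),
out-of-focus particles are filtered with a random-forest model on
morphometric features, stagnant *background* particles that recur across
consecutive frames are detected and removed, and the surviving crops are
classified with a small CNN that can reject out-of-distribution
particles. A synthetic scene generator with exact ground truth makes
every stage testable without instrument data.

## Synthetic scenes

The generator emulates the image stream of a flow-imaging instrument
with a 725 × 545 µm field of view sampled at 1.55 µm/pixel, giving
468 × 352 px frames (`round(725/1.55) × round(545/1.55)`); keeping the
instrument geometry means pixel-scale quantities (jitter bounds,
distance thresholds) transfer directly.

*Sprites.* Particles are parametric sprites — disks, 2:1 ellipses,
filaments, and colonies of small disks, plus rings and irregular blobs
used as out-of-distribution shapes.  Non-disk shapes are scaled so
their pixel area matches an equal-diameter disk, which makes
field-of-view (FOV) coverage a function of particle count and diameter
only.  A sprite's geometry randomness (filament angle, colony layout)
is fixed by a `shape_seed`, so a given spec always rasterizes to the
same pixels; defocus is a Gaussian blur of the rendered patch, while
the support mask always describes the sharp shape.

*Scenes.* Target particles receive a fresh sprite and position every
frame (they flow through the channel); background particles receive one
sprite and one base position for the whole sequence and are re-rendered
each frame with a displacement of at most `max_jitter_px` (default
12 px) — direction uniform, magnitude uniform on [0, bound].  An
alternative truncated-normal magnitude mode (mean 16.8 px, sd 11.5 px,
matching measured travel-distance statistics of stagnant particles) is
available for calibration experiments, as is a straight-line walk mode
in which background particles move by an exact, controlled number of
pixels per frame.  Frames are 8-bit grayscale with additive Gaussian
noise (default σ = 2 gray levels on a background level of 128).

Default target diameters are uniform on 6–16 µm with contrast uniform
on [−0.70, −0.25] (darker than background, as in bright field).  With
these defaults the three seeding densities used throughout the
evaluation protocol — 10/15/25 targets plus 3/5/8 background particles
per frame — cover about 0.3/0.5/0.8 % of the FOV, the incidence rates
the protocol is designed around.

The generator does **not** model optics (point-spread functions,
illumination gradients, dark-field modality), flow dynamics, autofocus
drift, or the texture of real plankton.  Tests passing on these scenes
therefore demonstrate algorithmic correctness and calibration of the
pipeline, not field-sample accuracy.

## Segmentation

The detector thresholds the absolute deviation from an estimated
background (global median by default, local median filter optionally),
applies morphological closing (radius 1 px), and extracts 8-connected
components filtered to [5, 50 000] px².  Crops are padded by 3 px.
Detections are scored against ground truth with five mutually exclusive
categories — true positive, false positive, false negative, merge,
split — using mask overlap: a truth particle is assigned to the ROI
containing ≥ 50 % of its support pixels; a particle intersecting two or
more ROIs is a split; an ROI with two or more assigned particles is a
merge; accuracy is true positives over ground-truth particles.  Mean
per-frame counts convert to concentration through the imaged volume
(FOV area × 200 µm channel depth).

## Feature catalog

Each ROI gets 47 named features (catalog version `reconstructed-v1`):
24 shape descriptors from region properties (area, perimeter variants,
axis lengths, eccentricity, solidity, extent, circularity = 4πA/P²,
convexity, Hu moments 1–4, bounding-box geometry, …), 15 intensity
statistics over the support (mean/max/min/sd/median, percentiles,
skewness, kurtosis, integrated intensity, contrast), and 8 edge-noise
statistics: mean absolute Sobel-gradient and Laplacian responses, both
over the support and over a 2-px band around the mask boundary
(`edge_noise_gradient`, `edge_noise_laplacian`).  The band statistics
are strongly blur-sensitive, which is what the focus classifier needs.

Pearson pruning greedily drops any feature whose absolute correlation
with an earlier-retained feature reaches the threshold (default 0.95);
zero-variance features are dropped with a warning.  Importance ranking
uses mean impurity decrease of a 200-tree random forest; rows are
canonically ordered before fitting so the ranking depends only on the
data multiset and the seed.

## Focus filtering

A random forest (200 trees, balanced class weights) is trained on the
feature catalog with a stratified 70:30 split, then retrained on the 12
top-ranked features.  The decision threshold on the predicted
out-of-focus probability defaults to 0.5 and is an explicit knob, since
degree of focus is a continuous quality and any binary cutoff sits
inside the overlap region of the two populations.  On synthetic
sharp/blurred pairs (σ ≥ 2 px) the partition accuracy exceeds 90 %;
edge-noise and gradient features dominate the importance ranking.

## Background-particle detection (BPD)

A particle stuck in the flow cell is re-imaged near the same position
in successive frames and would otherwise be counted repeatedly.  The
detector slides a three-frame window over the sequence and works in two
stages:

1. **Position clustering.** DBSCAN over the x–y centroids of all
   particles in the window, neighborhood radius
   `distance_threshold_px`, minimum cluster size 2.  Free-flowing
   particles land at fresh positions and are mostly labeled noise.
2. **Feature sub-clustering.** A moving particle can pass near a
   stagnant one, so each position cluster is split by single-linkage
   clustering with inter-particle distance = the worst per-feature
   discrepancy over a robust subset; links form below
   `feature_tolerance` (default 0.08).  The discrepancy is relative for
   features of magnitude > 1 and absolute below that, so bounded
   features such as eccentricity are compared on their natural scale.

A particle is flagged only when its sub-cluster spans at least two
distinct frames of the window (the 2-of-3 rule), and a particle's final
label is the OR over all windows containing it — the combination that
maximizes duplicate removal.

*Feature subset.* The default subset is (area, perimeter, eccentricity,
first Hu moment, median intensity, 75th-percentile intensity).  Shape
features are identical for re-rendered copies of a stagnant particle;
median and upper-quartile intensity were chosen over mean/sd because
they tolerate partial contamination when a flowing particle overlaps
the stagnant particle's crop — with mean/sd in the subset, such
overlaps caused missed detections at the higher seeding densities.

*Calibration.* `calibrate_tolerance` renders sequences whose background
particles move by an exact per-frame displacement and records the
detection rate.  The default `distance_threshold_px = 22` keeps
detection at 100 % on a 0–20 px displacement grid (comfortably above
the 95 % design target for movers up to 20 px, since consecutive-frame
displacement never exceeds ~21 px after rounding) while staying small
enough that coincidental position clustering of free-flowing particles
is rare; residual errors at the highest density are a handful of
false positives from sprite pairs that happen to agree in all six
features.

Evaluation is per particle: accuracy = correctly labeled particles over
all particles, false positives = valid particles flagged, false
negatives = background particles missed.  The evaluation harness feeds
the detector observations extracted at the ground-truth boxes of the
rendered frames (so feature values carry the scene's noise), which
isolates BPD behavior from segmentation merges; integration with the
real segmenter is exercised separately on well-separated scenes.

## Closed-set classification

The classifier is a "micro-CNN": one CONV + max-pool block, four
CONV + max-pool + dropout blocks (dropout 0.25), two dense layers, and
a softmax output; Adam (learning rate 10⁻³) with categorical
cross-entropy and inverse-frequency class weights.  Defaults are sized
for CPU training: 32 × 32 grayscale input, 3 × 3 kernels, channel
widths 8/16/32/32/64, 64 dense units, 30 epochs, batch 32.  Crops are
padded to square with the border median (no aspect distortion — the
morphology classes would be corrupted by anisotropic scaling) and
resized with anti-aliasing.

Datasets are split 70:15:15 per class; the training split alone is
expanded 8-fold with the dihedral transforms (rotations by 0/90/180/270°
of the image and its mirror — lossless, pixel-exact, identity
included).  The network engine (`fimflow.nn`) is a compact in-repo
numpy implementation (im2col convolution, 2 × 2 max pooling with
first-wins tie-breaks, inverted dropout, Adam) whose gradients are
verified against finite differences; all stochasticity flows through
explicit seeded generators, so training is bit-reproducible.

## Classification with rejection

All three methods expose the same contract — a label, a single scalar
score, and a rejected flag — so the analysis layer is method-agnostic.

* **SoftMax thresholding**: score = max class probability; reject when
  it falls below the threshold.
* **Monte-Carlo dropout**: 50 stochastic forward passes with dropout
  active; the mean probability vector is thresholded on its maximum,
  the same convention as SoftMax thresholding.  With dropout 0 a single
  deterministic pass is used, making the method exactly equal to plain
  prediction.
* **Class-anchor clustering (CAC)**: the head outputs a K-dimensional
  embedding; class anchors sit at 10 × the one-hot points.  The loss is
  a tuplet term (cross-entropy on negated anchor distances) plus 0.1 ×
  the distance to the sample's own anchor; prediction is
  nearest-anchor, the score is that distance, and rejection triggers
  when the distance exceeds the threshold.

Training with a *known out-of-distribution class* (KOC) — a catch-all
debris class — is an ordinary (K+1)-class fit whose KOC predictions map
to a null label at reporting time.

The report layer sweeps 101 evenly spaced quantiles of the observed
confidence distribution (confidence = score for softmax/MCD, negated
distance for CAC).  Precision and recall are computed over known-class
items only — rejected known items count against recall, not precision —
and each unknown group's rejection rate is its rejected fraction.  In
tests, "precision non-decreasing in threshold" tolerates at most two
adjacent-grid decreases larger than 0.01, the scale of single-sample
fluctuations near the top of the curve.

Synthetic unknown groups for these experiments are irregular
low-contrast blob sprites ("debris"-like) and ring sprites (a shape
class never trained on, "novel").

## Pipeline

Stages communicate through on-disk artifacts (PNG frames, CSV tables,
JSON reports), so each stage is independently runnable from the CLI
(`fimflow simulate|segment|features|focus-train|focus-apply|bpd|train|
predict|openset-eval|run`).  Filtering stages only remove particles,
and the run report records the seed and a config hash.

## Problem sizes and numerical choices

The shipped evaluation protocol uses 20 seeded sequences of 30 frames
at each of the three densities (≈ 40 000 particle observations) for
detection accuracy, and ≥ 200 particles per displacement on a 0–20 px
grid for the tolerance curve.  Classifier experiments use 200 images
per sprite class with seed-fixed training (18 epochs for the closed-set
model; 12–15 for the CAC and KOC variants, which converge faster than
the default 30 on these separable shapes).  Ties in max pooling and in
importance ranking break deterministically (first index / catalog
order); degenerate inputs (constant frames, empty masks, single-class
labels) raise informative errors or return empty results as documented
per function.

## Limitations

Sprites are far easier to classify and to match across frames than real
plankton imagery; accuracies on synthetic scenes are upper bounds, not
field estimates.  The background-particle detector assumes stagnant
particles keep a recognizable feature signature between frames — a
particle whose defocus changes sharply mid-run (autofocus events) can
escape sub-clustering.  The CNN engine is deliberately minimal: no GPU,
no batch normalization, no learning-rate schedules; it is sized for the
package's crop-classification task, not for general deep learning.
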