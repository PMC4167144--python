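# Methods

This note documents the models, parameters and numerical choices behind
`ifishquant`, and what the synthetic validation does and does not show.

## Image model and assumptions

Inputs are co-registered 2-D fluorescence channels (maximum projections;
no z-stack handling) with one mandatory DAPI channel. Intensities are
treated as non-negative and arbitrary in scale: every stage that depends
on intensity expresses its thresholds as *fractions of the observed
dynamic range* (watershed depths, spot-response thresholds, membrane
barriers), so the pipeline is invariant to affine rescaling of a channel.
Contrast adjustment (`autoadjust`, 1% tail saturation by default) exists
for display only; all quantification reads raw intensities.

## Nuclear segmentation

*Foreground.* Local entropy (disk radius 4, i.e. a 9×9 neighbourhood —
the neighbourhood size is a design choice, as is summing the two
min-max-normalised images) plus intensity, Otsu-thresholded; holes up to
64 px are closed.

*Iterative H-minima watershed.* The H-minima transform is implemented by
greyscale reconstruction by erosion of (inverted image + h) under the
inverted image. Depths run down a linear ladder of `n_depth_steps = 5`
rungs from 30% to 10% of the foreground dynamic range; only the 10–30%
window is prescribed by the method, the ladder shape is ours. Fragments
are triaged by a linear discriminant over 10 shape features; the two
deviation features are expressed *relative* to the expected nucleus
geometry so that one classifier works across magnifications. Optimal
fragments are frozen and removed from the working mask; everything at
the final depth enters the merge stage. Fragments below
`min_fragment_area` (500 px at 60x, scaled by (mag/60)²) are discarded
after merging; specks below 1/8 of that floor are dropped immediately.

*Expected nucleus geometry.* The 60x working range 2500–10000 px² is
summarised by its geometric mean (5000 px²); 20x/40x values scale with
the square of the magnification ratio (40x: 2222 px², inside the stated
250–3000 px² range). Both are config-overridable.

*Oversegmentation merger.* Features: pixelated solidity
(area / convex-hull-image area) and negated relative deviation from the
expected area. All subsets of the neighbours within `merge_radius`
(default 5 px between fragment boundaries; the radius is ours to choose)
are scored exhaustively; ties resolve to the smallest union first
encountered in lexical order, deterministically. Beyond 8 neighbours the
exhaustive enumeration (≤256 subsets) is replaced by greedy pairwise
merging with the same score, since the combinatorial rule is only exact
at small neighbourhoods. A merge is applied only on a strictly positive
maximum; with no neighbours or no positive score the fragment stays.

*Fragment classifier training data.* The shipped model is trained at
import time, deterministically (seed 0), on 153 synthetic fragments
balanced over the three classes: single ellipses (0.5–1.6× expected
area), fused/abutting pairs (undersegmentation archetype) and chord-cut
pieces (oversegmentation archetype). It is cached per nucleus scale and
retrainable from any labelled feature matrix via
`train_fragment_classifier`. The synthetic provenance of this training
set is a stand-in for manually scored watershed fragments.

*Connectivity* is 8-connected throughout; label maps always hold
consecutive positive integers with 0 as background.

## Membrane territories

The Voronoi partition assigns each pixel the label of the nearest
nucleus *region* via the Euclidean distance transform's feature map.
`membrane_segment` floods a watershed from the nuclei over the membrane
intensity with pixels at or above the 95th percentile raised above the
rest of the range so they act as barriers (the percentile is
configurable; the idea of pinning boundaries to bright edges is the
method's, the value ours). A perfectly flat channel short-circuits to
the Voronoi partition, which is also the limit the watershed approaches
as contrast vanishes. Membrane intensity is measured in a *band*: the
territory boundary dilated by 2 px, matching the ring phenotype of
membrane markers; the coefficient of variation over this band separates
complete from broken rings. Active-contour refinement (morphological
Chan-Vese or geodesic) ships disabled; a refinement that evicts the
region's nucleus is rejected and the region reverts.

## Spot detection and copy number

The LoG scale is derived from the minimum spot size,
σ = sqrt(min_spot_size/π)/√2 (≈1.55 px for 15 px at 60x); candidates are
pixels above 20% of the peak scale-normalised response. Gradient
confirmation requires a 3×3 regional maximum of the Sobel magnitude on
the candidate (or its 1-px halo) whose value reaches 15% of the region's
contrast per detection-scale pixel; this keeps sharp puncta and rejects
smooth autofluorescent mounds regardless of their absolute brightness.
Both fractions are design choices.

Spot *area* is measured as the half-maximum footprint: the connected
set of pixels above halfway between the region's peak (98th percentile
of region pixels for large regions, to resist shot-noise inflation of
the maximum) and a local base (10th percentile of a padded window).
This makes the area measure independent of the candidate threshold,
which is what the copy-number calibration of ~20 px per signal relies
on. Copy number is `round(total area / 20)`, coded 22 at or beyond the
400 px saturation plateau or above 21 copies.

Amplified clusters are too broad for the single-spot LoG scale, so a
second LoG pass at the cluster scale (the σ whose half-max footprint
equals the saturation area) flags broad bright regions; a flagged region
counts as a cluster only if it does not contain two or more
already-resolved spots (then it is a countable group) and its half-max
footprint exceeds 5 signals' worth of area. Resolved spots swallowed by
an accepted cluster are removed to avoid double counting.

The default intensity threshold is 0 (the expected-size filter does the
work on clean channels); an `"auto"` mode applies Otsu to candidate mean
intensities for channels with a genuine dim-artefact population. The
spot-shape classifier (LDA over the 10 shape features plus mean and
minimum intensity) is trained like the fragment classifier, on 67
synthetic spot candidates, and is off by default.

Spots attach to the nucleus containing their centroid; spots outside
every nucleus stay unassigned and are ignored in per-cell totals.

## Background correction

Global background is the mean over a user-supplied region (batch mode: a
mask file, or the complement of the segmented nuclei when none is
given). Ring background is the mean in the annulus between 2 and 6 px
outside each nucleus, excluding all nucleus pixels; annulus pixels
contested by two nuclei go to the nearer one (computed from one distance
transform rather than per-nucleus dilations). A nucleus with a fully
occluded annulus falls back to the global mean with a warning. The
margins are fixed pixels at every magnification, with a config override.
Corrected intensities clamp at zero, matching the convention that a
negative corrected intensity is reported as 0.

## Cell records, classification, thresholds, maps

Nuclear stains are measured over the nucleus; membrane stains over the
membrane band. A mapping inconsistency (one membrane region holding the
majority of two nuclei) raises an error naming the labels instead of
resolving silently. Cell typing uses a one-vs-all linear-kernel SVM,
C = 1, with features standardised on the training subset; morphology
features are area, perimeter, solidity, axis lengths and eccentricity,
and the intensity variant appends per-stain adjusted intensities and
spot area. Two to four classes are accepted (four matching the
interactive tool's limit; a batch override exists). Threshold rules
compare ≥ (boundary value is positive). The topology-map ratio is
a/(a+b) — a bounded form chosen for colormap stability since only a
"relative ratio" is prescribed — with a+b = 0 rendered neutral grey.

## Evaluation

Matching rule: a prediction correctly segments a gold object at Jaccard
≥ 0.5 (configurable; above 0.5 matches are provably one-to-one). A
prediction holding the majority of ≥2 gold objects marks those objects
undersegmented; ≥2 predictions each lying majority-inside one gold
object count one oversegmentation per extra prediction. Remaining
objects are false positives / negatives. The exact gold-matching
taxonomy of the original evaluation is not fully specified in the
available text; this rule is our documented approximation, and the
acceptance suite verifies it against an independent brute-force
implementation rather than against external data. Perimeters use
scikit-image's contour-length approximation, for which the square
scaling law (perimeter–area ratio halving under 2× scale) holds to a few
percent at realistic object sizes.

## Synthetic scenes

The generator emulates: dart-thrown elliptical nuclei (default 50 cells
of mean radius 26 px at 40x ≈ 2100 px², radius sd 3 px, aspect ≥ 0.7)
with a controllable fraction placed as abutting pairs at 95% of the
radius sum; per-nucleus DAPI domes (peak at centre, 40% falloff at the
boundary) so touching pairs present a watershed saddle; flat per-cell
nuclear-stain levels; membrane rings at 1.35× the nucleus with random
arc deletions totalling (1 − completeness) of the circumference;
Gaussian FISH spots whose half-maximum footprint is exactly 20 px,
placed non-overlapping inside eroded nuclei; amplified cells as one
contiguous cluster of 450–600 px half-max area; constant, linear
gradient or smooth random background fields (default level 0.10);
Poisson noise at 400 photons per unit intensity plus Gaussian read noise
(sd 0.01). All randomness flows from one seed; identical seeds give
bit-identical scenes.

Not emulated: tissue texture, sectioning artefacts, out-of-focus light,
chromatic shift, overlapping (not merely touching) nuclei, and intensity
variation within a phenotype class. Passing the synthetic recovery tests
therefore demonstrates correctness of the algorithms under controlled
conditions — saddle-separable touching nuclei, spots at the calibrated
scale — not performance on patient material, where boundary contrast and
artefact rates are far less favourable.

## Problem sizes and determinism

The test suite and acceptance script use scenes of 350–600 px and
10–50 cells, 100 random neighbourhoods/scenes per oracle-equivalence
check and 25–100 classifier resamples; these sizes were chosen so the
full validation completes in a few minutes while every check retains
enough cases to be meaningful. The pipeline itself contains no random
number generation — all stochasticity lives in scene generation and
resampling, each governed by explicit seeds — so batch runs are
bit-reproducible, which the acceptance suite asserts by hashing bundle
trees from two independent runs.

## Known limitations

- 2-D only; spot counts from projections undercount stacked signals.
- The merger's greedy fallback beyond 8 neighbours is not guaranteed to
  find the optimal subset.
- The shipped classifiers are trained on synthetic archetypes; real
  tissue benefits from retraining on a few manually scored fragments.
- Copy-number accuracy degrades when per-spot area deviates from the
  20 px calibration (defocus, chromatic blur); the per-spot measurement
  must stay unbiased to within ~1 px for exact counts at 10 copies.
- `match_segments` below an overlap threshold of 0.5 uses first-come
  greedy matching, which is order-dependent in ambiguous cases.
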