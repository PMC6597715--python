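# Methods

This note documents the models implemented in `skelsim`, the parameters
that matter, the choices made where the design was genuinely open, and
what the synthetic-data tests do and do not establish.

## Skeletal objects

A skeleton is three cubic Bezier segments in "virtual units" (vu).  The
root starts at the origin with its tangent along +y (toward the viewer).
Each child segment attaches to an earlier segment at a parameter drawn
uniformly from [0.1, 0.9]; its start direction is drawn uniformly on the
circle of directions perpendicular to the parent tangent at that point, so
the tangent-orthogonality invariant holds to machine precision.  Per
segment, the chord length and the bend magnitude (a perpendicular offset
applied to the third control point, which leaves the start tangent exact)
are drawn uniformly from [0.05, 0.25] vu; both draws are kept in the
segment metadata.  The finished skeleton is rescaled about its
bounding-box center so the longest bounding-box side is 0.25 vu — the
bounding box is measured on 256 dense samples per segment, making
normalization deterministic and idempotent (re-normalizing moves no
coordinate by more than 1e-12).

Increment morphs relocate one child segment along the central (root)
segment: step *f* moves the attachment arc-length position by *f* × the
central segment's length, translating the child rigidly.  The morphed
skeleton is deliberately **not** re-normalized, so the attachment-shift
invariant (new position = base + *f* × length to 1e-9) holds exactly and
the object's scale is untouched, as a physical relocation of a part would
leave it.  The three increment-series base objects use fixed
spatial-relation templates (children below / on either side / diagonal)
with the movable child attached in the first half of the root so the full
+50% series stays on the segment.

## Surface forms and rendering

A surface form is a circular-cross-section tube whose centerline is the
skeletal curve and whose radius follows a taper profile over normalized
arc length: two constant-radius forms (thin 0.011 vu, thick 0.022 vu —
the same profile family, differing only in circumference), a linear
taper-to-tip, a convex mid-segment bulge, and a concave pinch.  Radii are
floored at 0.0015 vu so profiles never collapse to a point.  Frames along
the centerline are propagated by parallel transport (no Frenet flips);
tubes from different segments may interpenetrate at junctions, which
silhouette rendering tolerates.

Rendering is deliberately minimal: orthographic projection along −y after
rotating the object about the vertical (z) axis by the trial's depth
orientation, flat Lambertian shading (ambient 0.25, diffuse 0.70, fixed
light direction), constant zero background, z-buffered rasterization into
a fixed world window of ±0.21 vu.  The analysis needs images whose
contours depend on skeleton, form and orientation — not photorealism —
and a pure-numpy rasterizer keeps renders bit-reproducible.

## The skeletal distance

Given two skeletons: 999 points per segment at equal parameter steps
(2997 total); per-segment arc-length respacing at 0.0005 vu with
coordinates rescaled ×1000 (spacing 0.5 in rescaled units, consecutive
distances within 2% by contract); center-of-mass overlay; a search over
the 24 picture-plane rotations (15° grid about the viewing axis, one
cloud rotated, ties to the smaller angle); and the mean Euclidean
closest-point distance at the best rotation.  The directed distance
(a→b) is not symmetric, so the default symmetrizes by averaging both
directions; a `directed=True` flag exposes the one-sided variant.
Respacing is per segment because junctions make a single global
arc-length parameterization ambiguous; a segment shorter than the spacing
keeps its two endpoints.  Closest points come from an exact O(nm) scan
for clouds up to 500 points and a k-d tree above that — both exact; the
tree only changes the complexity, and a test asserts bit-equality against
the double-loop oracle.

Note one geometric consequence of the alignment contract: because both
clouds are overlaid by center of mass before the rotation search, any
pure translation between two otherwise identical structures is absorbed,
and their aligned distance is zero.  The parallel-offset closed form
(mean distance = offset for two parallel polylines) therefore applies to
the pre-alignment closest-point kernel, and is tested there.

## Image models

Gabor kernels use conventional constants recorded on the bank object:
octave-spaced wavelengths from 4 px, bandwidth σ = 0.56 λ, aspect ratio
0.5, an even/odd phase pair, zero mean and unit norm after truncation
(kernels are capped at the image size).  Images are edge-padded before
convolution so constant images produce zero magnitudes and features are
invariant to global intensity offsets.

* **Gabor-Jet**: complex responses of the 5 × 8 bank read out at a 12 × 12
  node grid; the feature vector is all magnitudes followed by all phases,
  node-major then scale then orientation (11,520 values).
* **GIST**: energy (magnitude) maps of a 4 × 8 bank averaged within a
  4 × 4 spatial grid (512 values).  No local contrast normalization is
  applied by default; only the filter–pool stages are implemented.
* **HMAX**: S1 normalized-correlation Gabors at 8 sizes (7–21 px) × 4
  orientations; C1 max over adjacent sizes and local windows (8–14 px,
  stride half); S2 radial-basis template match against patches of C1
  (sizes 4/8/12 units × 4 orientations); C2 global max per template over
  positions and bands.  Template patches are cropped at random C1
  positions from a held-out set of rendered images with a fixed seed —
  the patch provenance (seed, source count) is stored on the patch set.
  HMAX dissimilarity is 1 − Pearson correlation of C2 vectors; the other
  models use mean Euclidean distance.
* **CNN adapter**: deep-network features are *read*, never computed —
  a validated CSV table keyed by (skeleton, form, orientation, layer).
  For self-contained runs a synthetic stand-in generator projects
  block-averaged pixels through a fixed random linear map with
  rectification; it is labelled synthetic and is not a CNN.

An object-pair RDM averages image-pair distances at matched surface form
and orientation over whatever (form × orientation) conditions the feature
set covers; the reference analyses use the thinnest form at three
orientations (three values per pair), which follows the "one value per
object pair, averaged over the three orientations" accounting of the
source workflow.  An all-crossings mode is not provided; matched pairing
is the only implemented convention and is stated here rather than
asserted as the original.

The decoding control trains a linear SVM (C = 1, features standardized
per fold) to label two objects from their images at non-test
orientations and tests on one orientation per object, over all 6
orientation pairings and every form; with three orientations this is 30
cells of 2 test items each, so pair accuracies are multiples of 1/60.

## Behavioral statistics

* Pair dissimilarity = proportion of "different" responses on that pair's
  different-object trials, pooled over participants; same-object trials
  only enter accuracy summaries.
* Model-human correlation: Pearson r; SE from 1000 bootstrap resamples of
  pairs; p from 10,000 permutations of the score vector over pairs,
  one-sided on |r| with the plus-one convention.  Calibration was
  verified by simulation: under null data the rejection rate at α = 0.05
  is 0.048 (the exact expectation with 499 permutations is 24/500).
* Noise ceiling: 1000 random half-splits of participants, correlating the
  two half-mean score vectors; the mean and the SD of the split
  correlations are reported, with no split-length (Spearman–Brown)
  correction.
* Joint regression: OLS on z-scored predictors; unique ΔR² per predictor;
  all two-predictor sub-fits for suppression checks.  Pairs are
  unweighted (every pair counts once regardless of observation count).
* Commonality analysis computes R² for all 2ᵏ − 1 predictor subsets and
  applies inclusion–exclusion; components sum to the full-model R² and
  this identity is asserted at 1e-10 on every call.  Redundant predictors
  are legal here (zero unique, fully shared components) though the joint
  regression rejects exactly collinear designs.
* The mixed model has crossed random intercepts (subject, object) and
  z-scored fixed effects.  The default link is identity — a linear
  probability model on accuracies, fitted by maximum likelihood with
  statsmodels' `MixedLM` (variance components for the crossed factors) so
  likelihood-ratio tests are exact to the fitted family; the identity
  LRT was cross-checked against lme4's `lmer` on the same data.  A logit
  link is available through lme4's `glmer` (via `Rscript`) when binary
  trial-level responses are analyzed; coefficients are then log-odds.
  **Small-sample caveat**: for a predictor that varies only across the 18
  objects, the χ²(1) reference is inflated (simulated null rejection
  ≈ 0.08 at α = 0.05 even with object variance present, worse when the
  object variance sits at the zero boundary).  Calibration checks
  therefore permute the predictor across subject × object cells, the
  regime the asymptotics cover; conclusions about object-level predictors
  at this scale should lean on the large observed χ² (≈ 40–50 under the
  default generator), not on borderline p-values.
* NAP clustering: k-means (10 restarts) over a k range, k chosen by mean
  silhouette; cluster-label-to-surface-form predictivity is majority-vote
  accuracy; its p-value shuffles the cluster labels 10,000 times
  (plus-one).  Conflict scoring reports per-participant accuracies and
  skeleton-choice proportions with one-sample t tests against 0.5 and
  Cohen's d, plus a per-surface-form breakdown.

## Synthetic participants

The discrimination simulator is an equal-variance signal-detection model.
Different-object trials carry evidence d′ + Σ w_m z_m(pair), where z_m is
the model's z-scored RDM value; same-object trials carry zero evidence;
Gaussian noise (SD 2.0 by default) is added per trial and the response is
"different" above the criterion at d′/2.  The baseline d′ is calibrated by
Brent bisection on the *analytic* expected accuracy — monotone in d′ — to
a target group accuracy of 0.80 (the observed human level used as a
realism anchor); the calibration is exact in expectation and lands within
±0.03 empirically.  A 2% lapse rate replaces the decision with a coin
flip at the configured guess bias.  Defaults weight the skeleton highest
(1.0 vs 0.5/0.35/0.3/0.3), encoding the recovery target that the analysis
stack must detect; noise SD 2.0 keeps pair-level accuracies spread over
(0.5, 1) rather than saturating.

The increment-series simulator draws same-trial accuracy from a logistic
psychometric function of z-scored skeletal distance (intercept 1.9, slope
−0.9: ≈0.95 correct at the 0% increment falling to ≈0.65–0.70 at 50%,
above chance at every level), with constant different-trial accuracy 0.85
and crossed subject (SD 0.4) and object (SD 0.25) intercepts on the logit
scale so the mixed model's random effects estimate real variance.  The
match-to-sample simulator answers skeleton-match, form-match and conflict
trials correctly / skeleton-ward with probabilities 0.88, 0.78 and 0.70,
jittered per participant (SD 0.15, clipped) — between-participant spread
keeps group effect sizes in a plausible range (conflict d ≈ 1.4 rather
than the >4 a homogeneous population would give).  Ratings for the 4 × 5
stimulus grid are drawn from four planted centroids on the four
non-accidental-property scales — the two constant-radius forms share a
centroid — plus Gaussian noise (SD 0.8), so five forms genuinely contain
a four-cluster structure.

Every simulator is byte-reproducible given its seed; outputs carry the
seed and an MD5 hash of the config.

## What the synthetic tests show — and what they do not

Passing recovery tests establish that the pipeline detects the structure
it was told to plant: dominant generator weight on the skeletal RDM is
returned as the largest unique variance component in ≥ 95% of seeds, a
negative psychometric slope appears as a significant negative mixed-model
coefficient, planted four-cluster ratings select k = 4, and null
configurations produce false-positive rates at the nominal level.  They
do **not** show that human observers weight skeletal structure this way:
the simulators implement exactly the linear-evidence assumptions the
analyses invert, real response data have sequential, attentional and
strategic structure the generator omits (by design — only a uniform lapse
is modeled), and rendered stimuli are matte, texture-free tubes.
Conclusions about real data require the real data.

## Numerical choices and problem sizes

Arc lengths use 2048-point chord tables (consistent to ~1e-12 between the
forward and inverse maps, which is what the increment invariant is tested
against).  Rotation ties break toward the smaller angle; k-means uses 10
restarts with seeds spawned from the call's seed; permutation and
bootstrap p-values use the plus-one convention throughout.  The reference
analyses and the acceptance script run the full 30-object set with
96-pixel renders, 25 HMAX templates and a 40-pair decoding sample;
test-suite fixtures use 64-pixel renders and smaller object sets.  These
sizes were chosen to keep a complete end-to-end run in the minutes range
on a single core while preserving every structural count of the designs
(150 objects, 2997 skeletal points, 885/435/450 and 648 and 480 trials).

## Known limitations

Bezier "curvature" is implemented as a single perpendicular control-point
offset — a one-parameter bend family, not the full space of cubic
curvature profiles.  The rotation search covers the picture plane only,
with no continuous refinement and no reflections, and rotates one cloud
(a second search axis is redundant for a single picture-plane axis).  The
renderer has no texture, cast shadows or perspective.  The GIST variant
omits the pre-filtering stage of the full descriptor.  HMAX templates are
built from this package's own renders, not any distributed patch set, so
absolute C2 values are not comparable across patch provenances.  The
identity-link mixed model treats binary accuracy linearly; for
trial-level inference the logit backend is preferable when R is present.
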