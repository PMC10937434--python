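# Methods

## Problem and approach

Quality assurance of organ-at-risk (OAR) contours is framed as one-class
outlier detection: for each OAR type, models are fitted only to acceptable
contours, and a new contour is flagged when it deviates from that learned
distribution. Three complementary detector families run per contour and
are combined by logical OR:

1. **Single-contour feature models** (z-score, Mahalanobis distance,
   autoencoder) on a 20-feature description of one mask;
2. a **contour-to-contour relationship (CCR) model** that bounds the
   minimum separation and fractional overlap of configured organ pairs;
3. a **connectedness model** that bounds the number of disconnected parts.

The OR combination exploits the complementary error coverage: gross shape
or position anomalies move the single-contour features, broken anatomical
relations (a gap where organs should touch, overlap where they should be
apart) trip the CCR bounds even when per-contour features look ordinary,
and stray single-slice fragments are caught exactly by the parts count.

## Features

All geometry is computed on voxel-centre coordinates in physical mm, so
anisotropic spacing (2 mm slices vs ~1.3 mm in-plane) does not distort
orientation. The 20 single-contour features are: centroid x/y/z relative
to the brainstem centroid (pituitary reference for the brainstem itself,
so its own position stays informative); the x/y/z components of the first
and second principal-component eigenvectors of the voxel cloud; volume
[cc]; covariance-eigenvalue ratios λ₂/λ₁ and λ₃/λ₁; x/y/z extent (span of
voxel centres — a single voxel has zero extent); Wadell sphericity
π^⅓(6V)^⅔/A with A from a marching-cubes surface after half-voxel
Gaussian anti-aliasing (a raw binary iso-surface overstates smooth-organ
area by ~9% through staircasing); and min/max/mean/sample-std of the CT
numbers under the mask.

Eigenvector signs are arbitrary, so each OAR stores a representative
eigenvector — the training member maximising the summed absolute dot
product with all others, ties to the lowest index — and every vector is
flipped to have non-negative dot product with it before modelling.

Pairwise features are the minimum distance between voxel centres (0 when
masks intersect; computed with a Euclidean distance transform at physical
sampling) and the directional fractional overlap |A∩B|/|A|. A
`prune_correlated` helper (greedy removal of |Pearson r| > 0.7 pairs,
dropping the member with the larger mean absolute correlation) is provided
for users extending the feature set; the shipped 20 features are already
the pruned set.

## Models and parameters

* **MAD filter** — a training row is discarded when any feature deviates
  from its per-OAR median by more than k = 12 unscaled median absolute
  deviations (≈ 8 σ for normal data); zero-MAD features are skipped.
* **z-score** — max over features of |x − μ|/σ (sample σ); a zero-variance
  feature that moved at all maps to +∞ (always flags).
* **Mahalanobis** — D(x) = (x − μ̂)ᵀΣ⁻¹(x − μ̂), the squared form without a
  root: thresholding is monotone-invariant, so classification is
  unaffected and the quadratic form is cheaper and numerically cleaner.
  Σ is the sample covariance plus δ·(tr Σ/d)·I with δ = 10⁻⁶, keeping the
  inverse finite for rank-deficient corpora.
* **Autoencoder** — 20 → 18 → 20 with sigmoid hidden units and linear
  output, trained on per-feature z-scores. Loss = mean squared
  reconstruction error + 0.005·Σw² over both weight matrices (biases
  unpenalised). Optimiser: full-batch gradient descent with a
  backtracking adaptive step (a step that would increase the loss is
  halved and retried; accepted steps grow the rate by 5%), so the loss is
  non-increasing by construction and training is deterministic given the
  seed. Stopping: 7000 epochs, relative loss change < 10⁻⁹, or step
  underflow. Note that the L2 penalty makes perfect reconstruction
  suboptimal: for unit-variance inputs the regularised optimum floors the
  reconstruction error around a few percent of the input variance, which
  is why capacity checks in the tests disable the penalty.
* **CCR bounds** — training distances are clipped to ≥ 0.01 mm and fitted
  to a gamma distribution (maximum likelihood, location 0); overlaps are
  clipped to [10⁻⁴, 1−10⁻⁴] and fitted to a beta distribution. Bounds are
  the 0.005/0.995 quantiles (a two-sided reading of "99th percentile
  boundaries"), expanded by 2 mm (distance) or 0.02 (overlap) so
  clinically irrelevant wiggle is ignored, then clipped to the feature
  domain (clip after expansion). An (almost) constant training sample —
  e.g. all distances zero for touching organs — yields point-mass bounds
  value ± expansion. After fitting, bounds are widened so that no
  acceptable validation pair falls outside them, the automated analogue
  of setting percentile boundaries by hand to minimise validation false
  positives. A flagged pair flags *both* member contours: the model
  detects an improper relationship, not which contour caused it.
* **Connectedness** — parts counted with 26-connectivity (matches the
  clinical perception of a separate blob). All-equal training counts give
  that value as the maximum; otherwise a gamma fit's 99.95% quantile
  (ceiling) allows legitimately multi-part organs (thyroid lobes,
  scan-truncated structures) without opening the door to ditzels.
* **Threshold tuning** — candidate cuts are midpoints of sorted unique
  validation metrics plus ±∞; the balanced-accuracy-maximising threshold
  is chosen with the CCR/connectedness flags held fixed, ties resolving to
  the higher threshold (favouring specificity). One global threshold per
  model type is used across OARs (per-OAR overrides are possible through
  the bundle's `tuned_thresholds`). The test split always reuses
  validation thresholds.

Contours from sets without a CT image are excluded from training; at
inference their CT features impute to the training mean, contributing
nothing, so geometric screening remains available.

## The phantom

The synthetic generator emulates the *structure* of a clinical
head-and-neck structure set, not its photorealism: 17 organs (ellipsoids,
tubes, boxes, paired lateral organs, a two-lobed thyroid) on a
76×76×72 grid at 1.27×1.27×2 mm spacing, plus a body cylinder and a
synthetic CT (per-tissue mean HU + per-patient HU jitter + Gaussian noise,
smoothed by a 0.7-voxel PSF).

Patient-to-patient variation has three layers chosen to reproduce the
regime that motivates relational features — *absolute* organ positions
vary much more than *local* relations:

* global scale ~N(1, 0.05) (≈ ±10% patients) and per-organ, per-axis
  scale jitter (σ 0.04);
* regional postural offsets (σ 4 mm) shared by the mid-face and neck
  organ groups (head pose, neck flexion) on top of small per-organ jitter
  (σ 1.5 mm) and oblique per-organ base orientations with ±4° jitter;
* hard anatomical attachments: the cord abuts the brainstem (4 mm shared
  depth), each lens is nested in its eye, the submandibular glands and
  oral cavity abut the mandible, the thyroid abuts the larynx. These
  relations hold by construction in every generated set.

Organ semi-axes differ by ≥ 15% so scale jitter cannot swap principal
axes between patients — perfectly symmetric organs would make orientation
features degenerate, which real anatomy never is.

The error injector implements four clinically motivated categories, each
at two severities: boundary (isotropic or one-sided/sectorized dilation
or erosion; moderate 2 mm, major 4–6 mm), volume (convex blob added or
removed, or terminal slices truncated; moderate 10–20%, major 30–50%),
non-adjacent slice (a single-slice disconnected fragment placed ≥ 5 mm
but near the organ, like a misclick, or jagged per-slice shifts for
major), and position (translation 10–15 mm moderate / 25–35 mm major, or
a swap with another organ's mask). Magnitudes are artifact-defined since
no clinical quantification exists; an error that would (almost) empty the
mask is rejected. Validation/test corpora draw categories in the
proportion 74 : 99 : 14 : 40 (boundary : volume : slice : position) and
severities roughly evenly, the clinically observed mix.

### What the phantom does and does not show

Passing the end-to-end study demonstrates the machinery — feature
stability, one-class fitting, bound calibration, threshold tuning, flag
combination — under controlled conditions with known ground truth. It
does not demonstrate clinical performance: real contours have textured
CT, inter-observer delineation variation, pathology-driven anatomy
changes, and far subtler errors. Two known quantitative differences:
the MAD filter removes ~5% of phantom training rows (mostly via CT
extremes and orientation tails sharpened by the phantom's clean geometry)
versus 0–3.6% reported on curated clinical data, and absolute AUC/BA
values on the phantom run higher than clinically reported values because
the injected errors are, on average, blunter than hand-crafted clinical
ones.

## The study design

`run_phantom_experiment` generates 100 sets, splits 80/10/10, trains on
the 80, injects 100 errors into validation and 30 into test (evaluating
each erroneous variant inside its own structure set so CCR comparisons
run against the set's remaining acceptable contours), tunes thresholds on
validation, and reports per-model metrics for both splits. Sizes were
chosen to keep a full study within a few minutes on one CPU while giving
each OAR type 80 training contours.

Because the CCR bounds are widened to produce no validation false
positives, OR-combination can never lower validation balanced accuracy;
whether it *strictly* improves all three single models depends on the
random error draw containing relational-only-detectable errors (e.g. a
moderate dilation into an abutting neighbour, a moderate displacement of
a gland with a tight pair). At the default seed the improvement is strict
for all three models; across replicate seeds it is strict in most runs
and ties on one model in some — the qualitative conclusion (combination
helps, driven by the high-specificity relational checks) is stable.

## Numerical and degenerate-input choices

* Rasterisation is voxel-centre-in-polygon (DICOM) or
  voxel-centre-in-analytic-shape (phantom): deterministic and standard.
* A single label volume cannot represent nested contours, so phantom
  corpora persist as per-set 4D mask stacks (NIfTI) plus a manifest CSV;
  the 3D label-volume reader remains for external data.
* Model bundles persist as versioned JSON; Python's float formatting
  round-trips doubles exactly, so reload is bit-exact.
* Bundles refuse to train on fewer than 10 contours per OAR rather than
  silently underfit; empty masks, missing reference contours (brainstem /
  pituitary) and mismatched grids raise immediately.
* ROC AUC is computed by midranks (ties count half), identical to
  pairwise concordance; the mid-p McNemar test is
  2·P(X ≤ min(b,c)) − P(X = min(b,c)) for X ~ Binomial(b+c, ½), p = 1
  with no discordant pairs.

## Known limitations

* The phantom's CCR matrix and organ roster are its own defaults;
  institutional deployments must supply their own pair matrix and alias
  table (structure naming varies widely).
* One global threshold per model type assumes output metrics are
  comparable across OARs; Mahalanobis values are scale-sensitive to
  covariance conditioning, and heterogeneous corpora may prefer per-OAR
  thresholds.
* CCR evaluation flags both members of a bad pair, so a reviewer
  inspects two contours per violated relationship; pairwise checks are
  also computed against possibly-erroneous neighbours in real use,
  whereas the study evaluates each injected error against acceptable
  comparisons only.
* Shrink-type moderate errors (erosion, small volume removal) that break
  no relation remain the hardest class for every model, on the phantom as
  in clinical reports.
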