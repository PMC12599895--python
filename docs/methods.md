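# Methods

`subtracad` implements a temporal-subtraction CAD pipeline for screening
mammography: the prior exam is deformably registered onto the recent one
and subtracted, so anatomy that is unchanged between rounds cancels and
newly developed tissue survives as a bright residual.  Candidate masses
segmented from the residual are described by a fixed 98-feature vector,
filtered by a consensus of eight feature rankings, and classified in two
rounds — candidate vs. normal tissue, then benign vs. malignant — under
patient-wise cross-validation.  Because clinical screening archives with
two annotated rounds per patient are not publicly available, the package
ships a seeded phantom generator that emulates the cohort structure such a
study uses, so every stage is testable end to end.

## Synthetic cohort (phantom)

Each patient contributes CC and MLO views in two rounds.  The breast is a
half-ellipse anchored on the chest-wall edge; base brightness rises
dome-like toward the interior, and fibroglandular texture is band-pass
filtered Gaussian noise (passband ≈1.5–6 px) whose amplitude grows with
BI-RADS density class (a: 0.02, b: 0.045, c: 0.075, d: 0.11 on the [0,1]
intensity scale).  Density classes are drawn 11/45/39/5 per 100 and the
patient mix is 35% normal / 15% benign / 50% malignant, matching the
population structure of a two-round screening study of 100 women.

Between rounds the anatomy is displaced by a smooth random field (sum of
three Gaussian bumps, peak magnitude 6 px by default) standing in for
positioning and compression differences, a global multiplicative gain
drift of up to ±4% is applied, and Gaussian noise (σ = 0.01) is added to
both rounds.  The exact field is stored before noise, so registration
recovery can be scored against it.

Masses appear only in the recent round (the "new mass" presentation that
motivates temporal subtraction).  Boundaries are radial functions
r(θ) = r₀·(1 + Σ aₖ cos(kθ + φₖ)): benign masses use low orders (k = 2, 3,
amplitudes ≤ 0.08), giving smooth near-circular blobs, while malignant
masses use high orders (k = 6…12, amplitudes ≤ 0.32), giving spiculated
stars — the radiological shape prior that makes shape features
discriminative.  Benign patients carry three masses per view and malignant
patients one, which reproduces the near-parity of benign and malignant
mass-level counts that a 15/50 patient split with multi-focal benign
disease produces.  Masses are placed with centers at Euclidean depth
> 1.4·r_max + 22 px inside the breast and mutually separated, so that a
correctly implemented peripheral-removal step cannot clip a true lesion;
placement failure after bounded retries raises a degenerate-geometry
error.  Mean in-mass brightness exceeds the local background by a
configurable margin (0.25 peak).

What the phantom does **not** model: X-ray physics, scatter, vendor
post-processing, pectoral muscle, calcifications, and masses that shrink
or vanish between rounds.  Passing tests therefore demonstrate the
pipeline's mechanics and its statistical machinery, not clinical
performance on real mammograms.

## Pre-processing

CLAHE (clip limit 0.01, 8×8 tile grid) → gamma correction (γ = 1.2,
applied on the normalized [0,1] scale) → border removal, in that order.
Border removal thresholds at half the Otsu level — the skin-line band of a
breast is much darker than its interior, and a full Otsu cut erodes it —
then opens with a disk of radius 5 (removing thin frame lines and labels),
discards thin components hugging several image edges, keeps the largest
component, and seals residual threshold cracks with a closing (disk 7)
plus hole filling so the mask is simply connected.  All intensities live
in [0,1] internally; conversion to the stored bit depth happens only at
I/O boundaries.

## Registration

The prior (moving) image is registered to the recent (fixed) image with
symmetric-forces Demons over a 3-level pyramid (shrink 4/2/1, iterations
100/50/25) with Gaussian field smoothing of σ = 3 px each iteration.  The
moving histogram is first matched to the fixed image (256 levels, 7 match
points): Demons assumes brightness constancy, which gain drift and
per-image adaptive equalization break.  The smoothing scale was set to the
smoothness of the simulated positioning/compression fields — on such
fields σ = 3 roughly halves the endpoint error relative to σ = 2, and
symmetric forces improve further on one-sided forces.  If the Demons
solution ever raises the mean squared difference above the unregistered
baseline, the identity field is returned instead, so registration never
degrades a pair.  A 6-parameter affine baseline (dense mean-squares
metric, LBFGS, B-spline interpolation) is included for comparison; on
elastically deformed pairs Demons consistently attains the lower residual.

## Subtraction and metrics

The residual is max(recent − warped prior, 0) inside the breast mask —
negative differences are clipped because the clinically relevant signal
here is *new* tissue, which is brighter in the recent round; disappearing
structure is out of scope.  Pixels where the warped prior has no support
(outside its breast mask or warped out of frame) are zeroed, since a
difference against nothing is not evidence of change.  Conspicuity is
quantified by the contrast ratio (mean intensity over the lesion mask
divided by mean over a background mask, background floored at 10⁻⁶) and
the percent background-intensity reduction, 100·(1 − after/before).  The
background region used is the breast interior minus the dilated lesion
masks.

## Candidate detection

Three steps, each idempotent on its own output: (1) thresholding — by
default an Otsu split of the nonzero residual values, which adapts to
lesion load (a fixed high percentile rations a pixel budget that a
multi-mass exam exceeds); a percentile rule (default q = 87) remains
available; (2) morphological cleanup — closing (disk 2) to reconnect
fragmented spiculated responses, opening (disk 1), hole filling, and
removal of components under 40 px; (3) peripheral removal — components
whose centroid lies within 12 px (Euclidean distance transform) of the
breast boundary are discarded, removing skin-line registration artifacts.
Surviving 8-connected components become candidate ROIs, matched to ground
truth by best IoU with a lenient 0.1 threshold (detection is counted
per mass, not per pixel).  On default settings the full pipeline retains
100% of inserted masses while passing ≈3 false-positive candidates per
image to the first classification round — the round that exists to prune
them.

## Features (98, frozen order)

* **GLCM, 72** — statistics {correlation, contrast, energy, homogeneity} ×
  distances {1, 2, 4} px × slots {0°, 45°, 90°, 135°, mean, SD over
  angles}.  Pixels inside the ROI mask are quantized to 16 levels over the
  ROI min–max; the matrix is symmetric, normalized, and co-occurrences
  with the out-of-mask level are dropped.  A zero-variance (constant) ROI
  has correlation defined as 0, contrast 0, energy 1, homogeneity 1.
* **First-order statistics, 10** — mean, SD, variance, skewness, kurtosis,
  entropy (bits, 64-bin histogram over the ROI range), energy, median,
  1st and 99th percentiles.
* **Intensity, 4** — maximum, mean, minimum, range.
* **Shape, 12** — area, perimeter, major/minor axis length, eccentricity,
  orientation, equivalent diameter, extent, convex area, filled area,
  solidity, circularity 4πA/P².  Computed in pixels; physical units are
  available through the optional pixel spacing.

`resolve_feature_name` maps report-style names ("Correlation 90° D2",
"Maximum intensity", "STD") onto the frozen catalog.

## Feature selection

Eight rankers span univariate and multivariate criteria: absolute Welch
t statistic, Wilcoxon rank-sum, mutual information, chi-square on
quantile-binned features, Fisher score, ReliefF (k = 10 neighbors, all
samples, [0,1]-scaled distances), mRMR (mutual-information difference on
4-bin quantile discretization, greedy), and random-forest impurity
importance (200 trees).  Non-finite scores (0/0 on constant features)
rank last; ties break by catalog order.  A feature is selected when it
appears in the top-K of at least 5 of the 8 rankings; K is either fixed or
tuned per fit so the consensus reaches a target size (19 features for the
candidate round, 17 for the benign/malignant round — the selection sizes
such a two-round design reports).  The selector is an sklearn transformer
and is refitted inside every training fold.

## Classification

Round 1 separates candidates into normal tissue vs. mass; round 2
separates masses into benign vs. malignant.  The suite: LDA, k-NN (k = 11
round 1, k = 5 round 2), RBF-SVM, random forest, MLP, AdaBoost, bagging,
gradient boosting, a soft-voting ensemble (k-NN+SVM+MLP+AdaBoost+GB in
round 1; LDA+RF+GB in round 2), and a neural network with 5 hidden layers
(round 1) or 1 (round 2) of 128 ReLU units, Adam, batch 128, learning rate
10⁻⁴, up to 100 epochs with early stopping on a validation split and L2
weight decay (α = 10⁻³) as regularization.  Features are standardized
from training-fold statistics for every model except the round-2 network,
which consumes raw features as an additional overfitting guard on the
small mass set.  Class imbalance is corrected inside the training fold
only, by SMOTE: synthetic minority samples are convex combinations of a
minority sample and one of its k = 5 nearest minority neighbors.

Cross-validation is patient-wise: leave-one-patient-out by default, or
grouped k-fold where folds partition patients (never ROIs).  Selection,
standardization, SMOTE and fitting are all redone inside each training
fold; a training fold reduced to a single class is recorded and skipped.
Pooled test predictions yield sensitivity, specificity, accuracy (all %),
trapezoidal AUC, Matthews correlation, Cohen's kappa, and bootstrap
percentile 95% CIs (2000 resamples, seeded) — the CI method is a design
choice of this package.  Classifier pairs are compared with the McNemar
test on discordant predictions (exact binomial below 25 discordant pairs,
continuity-corrected chi-square above), extended to a classifier suite as
all-pairs comparisons with Holm correction.

## Numerical and design notes

* Geometry is 0-based, row-major; bounding boxes half-open; displacement
  fields are (2, rows, cols) with warped(x) = moving(x + u(x)) and
  backward linear resampling (out-of-domain → 0).
* One global run seed fans out per stage and patient through
  `numpy.random.SeedSequence`, so identical config + seed reproduce a run
  bit-for-bit at the stored precision.
* k-NN neighbor counts are capped at the training-set size; MLP early
  stopping is disabled below 40 training samples, where a stratified
  validation split is not viable.
* Epoch semantics: an epoch is one pass over the training fold, i.e.
  ⌈n/batch⌉ Adam steps.  The network's schedule (100 epochs, batch 128)
  amounts to ~1600 steps on a cohort-sized candidate set but to only ~100
  steps on a small phantom fold, which leaves the fixed 10⁻⁴ learning
  rate severely under-trained.  The classifier therefore trains the
  network for the equivalent *step* budget (1600 steps) whenever the
  configured epochs fall short of it; learning rate, batch size and
  architecture are never touched, and an explicit `max_iter` override
  disables the adjustment.
* Problem sizes in tests and in the acceptance script (images 256×208,
  cohorts of 16–50 patients, 10 registration pairs, 20 selection seeds)
  were chosen as the smallest sizes at which each property is stable
  across seeds.

## Known limitations

Phantom realism is structural, not radiographic; the registration
parameterization is tuned to smooth synthetic fields and will need
re-tuning for real compression differences; vanishing or shrinking masses
are invisible to the one-sided residual by design; and two-round
classification quality on the phantom reflects the generator's shape
priors, not clinical difficulty.
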