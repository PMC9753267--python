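# Methods

This note documents the models, conventions and design choices behind
`plaquekit`, in the order the pipeline runs.

## The staging problem

Atherosclerotic plaque in CARS images appears as bright clusters of
lipid-laden foam cells on a dim background. Disease progression changes
the morphology of those clusters: early fatty streaks (EFS) show many
small, scattered, faint lipid pools; early fibroatheroma (EF) shows larger
pools coalescing, with a sporadic mixture of immature (dim) and mature
(bright) deposits that makes its intensity histogram the most asymmetric of
the three stages; advancing atheroma (AA) shows a dense, compact, bright
accumulation. The pipeline turns each image into a 27-number morphological
description, refines that panel to the features that actually vary between
stages, and classifies.

## Synthetic phantoms

Real curated CARS datasets of staged plaque are not generally available, so
the package generates phantoms that emulate the statistical structure of
the three stages. Each phantom is a 128×128, 16-bit image (geometry is in
pixels; no physical pixel-size calibration is assumed). Foam-cell clusters
are isotropic Gaussian-profile discs with amplitude `A`, profile scale
`σ = r/2` and a hard support disc of radius `r = 2σ`; the union of supports
is the ground-truth mask. Blob signals add where they overlap. The signal
sits on a background level of 1500 counts and receives Poisson shot noise
plus Gaussian read noise (sd 300), then is clipped to `[0, 65535]`.

Per-stage defaults (the "strong separation" preset — also the default
configuration):

| stage | blobs (mean±sd) | radius (px) | amplitude | layout |
|-------|----------------|-------------|-----------|--------|
| EFS | 25 ± 5 | 4 ± 0.8 (image) ± 0.8 (blob) | 12000 ± 1500 | uniform scatter |
| EF  | 18 ± 4 | 7 ± 1.5 ± 0.8 | mixture: dim 14000 ± 1500, bright 30000 ± 2000 | 2 loose clusters (sd 18 px) |
| AA  | 14 ± 3 | 11 ± 1.5 ± 1.0 | 32000 ± 2500 | 1 tight cluster (sd 14 px) |

These values were chosen once so that (i) expected foreground amplitude is
strictly ordered EFS < EF < AA (validated at configuration time), (ii) the
fraction of foreground in the largest connected component (compactness)
increases with stage, (iii) mean intensity, integrated density and area
separate by well over the 8% interclass CV used downstream, and (iv) EF is
built as a per-image mixture — each image draws a bright-blob fraction from
Uniform(0.1, 0.9) — so EF both carries the highest skewness/kurtosis and
genuinely overlaps its neighbours: some EF images are nearly all-dim
(EFS-like), some nearly all-bright (AA-like). This keeps EF the hardest
class, as it is in real staging.

What the phantoms do **not** model: optics (no point-spread function or
CARS contrast mechanism), collagen or any second channel, 3-D structure,
uneven illumination, or tissue autofluorescence. Passing tests on phantoms
therefore demonstrates that the pipeline recovers a staging signal of this
morphological kind, not performance on real tissue.

Determinism: every record is a pure function of `(config, stage, seed)`;
datasets derive per-record child seeds from one stream and shuffle
reproducibly.

## Preprocessing

Percentile contrast stretch (saturating the bottom and top 1% by default,
the common default of histogram-stretch routines) followed by unsharp
masking (`radius` 1.5 px, `amount` 0.8). All arithmetic is floating point,
rounded and clipped back to the integer grid once per operation. A constant
image passes through unchanged (no stretch is defined).

The stretched image drives **segmentation only**. The morphology panel is
measured on the acquired intensities: a per-image full-range stretch is a
normalization that would erase the absolute between-stage intensity
differences (mean intensity, integrated density) the staging signal relies
on.

## Segmentation

Mask polarity is foreground = plaque = high intensity; connectivity is
8-connected throughout (standard for blob-like microscopy objects).

* **OTS** — the Otsu criterion computed explicitly over a 256-bin
  equal-width histogram: the threshold maximizes the between-class variance
  `w0·w1·(μ0−μ1)²` over all split points (the implementation is checked
  against an exhaustive split-search oracle and against scikit-image).
  A constant image has no threshold and raises.
* **IFCT** — a permissive global seed threshold (75th percentile) proposes
  candidate clusters; each candidate's bounding region is re-thresholded
  with its own local Otsu, so dim clusters are segmented independently of
  bright ones; region masks are unioned, objects under 10 px dropped.
  Candidates whose peak is less than 4 robust sigmas (median + 4·1.4826·MAD)
  above the background are rejected — a quantile threshold always marks
  something, even on a plaque-free noise field.
* **MCW** — watershed of the Sobel gradient of the smoothed image (σ = 2),
  with markers at regional maxima separated by ≥ 8 px and the
  below-threshold region acting as background. The flood is confined to the
  above-threshold support: if the background marker is allowed to flood
  freely it claims every blob's dim skirt up to the gradient crest (the
  profile's inflection circle), roughly halving the mask. Confining the
  watershed keeps the gradient ridges where they matter — cutting the
  boundaries between touching clusters — which is the standard
  marker-controlled construction for microscopy.
* **KMS** — per-pixel features are Gaussian-smoothed (σ = 3) magnitudes of
  a Gabor bank (frequencies 0.05/0.1/0.2 cycles per px × orientations
  0°/45°/90°/135°) plus intensity; channels are standardized and the
  intensity channel up-weighted ×2.5, because with unit weight the twelve
  texture channels swamp intensity and their spatial support smears small
  EFS blobs. Seeded k-means with k = 2; clusters brighter than the image
  mean are plaque.

**Reference masks and Dice.** Phantom truth masks serve as ground truth;
for real images without truth, a Chan–Vese-type morphological active
contour evolves a dilated Otsu mask. Dice is `2|A∩B|/(|A|+|B|)`, defined as
1.0 when both masks are empty (agreement on absence). Dice is evaluated on
a seeded random subset of up to 50 images per stage.

On the default preset the mean Dice over 51 phantoms is ≈ 0.73 (OTS),
0.73 (MCW), 0.78 (KMS) and 0.68 (IFCT) — OTS and the texture methods ahead
of IFCT, which mirrors how these segmenters rank on real CARS data.

## The 27-feature panel

Canonical order: 6 first-order statistics, 4 shape descriptors, 17 texture
statistics.

*First-order*: mean intensity; number of objects (8-connected components of
the mask); skewness and kurtosis as population-standardized central moments
(kurtosis in the Pearson convention, normal = 3); sample (n−1) standard
deviation; integrated density (sum of masked intensities). Zero-variance
regions set skewness and kurtosis to 0.

*Shape* (on the mask union): area in px²; perimeter by the weighted
boundary-segment estimator (so a large digital disc has circularity ≈ 1);
circularity `4πA/P²`; extent = area over bounding-box area.

*Texture*: the gray levels are re-quantized to 32 equal-width bins over the
image's min–max (keeping 9×9 windows from being vanishingly sparse at 16
bits); a 9×9 window slides over every in-mask pixel (mirror padding at
image borders); per window a symmetric, normalized co-occurrence matrix is
accumulated at distance 1 for each of the four orientations; the 17
statistics are computed per offset, averaged over offsets, then averaged
over windows. Indices are 1-based in the moment-type statistics; logs are
natural with 0·log 0 = 0. Degenerate matrices give correlation 0, IMC1 0,
IMC2 0. Two numerical identities are exploited for speed and verified
against a naive double-loop implementation to 1e-10: cluster shade and
prominence are central moments of the sum distribution (binomial
expansion), and HXY1 = HXY2 = HX + HY because the joint and the product
measure share marginals.

## Feature refinement

* **CV selection** (the refinement method of interest): per feature, the
  coefficient of variation of the three class-conditional means,
  `CV% = 100 · sd(means; n−1) / mean(means)`; features with CV% strictly
  above 8 are retained. The score is scale-invariant, so normalizing
  features first would change nothing. A feature whose grand mean is
  exactly 0 has an undefined CV; it is scored +∞ and retained with a
  warning. Selection uses class means over the full labelled table, which
  is how the interclass statistic is defined.
* **FTF selection**: each feature is discretized into 10 equal-frequency
  bins (degenerate bins merge); the chi-square statistic of the
  bins × classes contingency table ranks features by ascending p-value
  (ties: descending statistic, then canonical order); the top 15 are kept.
  No multiple-testing correction — this is a ranking, not an inference.

## Classification

Class encoding is fixed: EFS = 0, EF = 1, AA = 2. The 60/20/20
train/test/val split is stratified (falling back to a plain split when a
class is too small to stratify) and seeded.

Hyperparameter tuning is a seeded random search (default budget 30) over:
kNN — neighbour count 1–30 (clamped to the feasible fold size), metric
(Euclidean/cityblock/Chebyshev/cosine), vote weighting; decision tree —
depth, leaf size, split size, leaf-node count; one-vs-one SVM — C, kernel
scale, kernel (RBF/linear). Configurations are scored by mean
misclassification loss under stratified tenfold cross-validation within the
training partition only (folds capped at the smallest class count);
infeasible configurations are skipped; the best configuration is refit on
the full training set. Random search behind a fixed interface keeps the
trace reproducible; a Bayesian optimizer could be substituted without
changing the contract. Distance-based models (kNN, SVM) standardize
features internally; the tree consumes raw features.

The multiclass SVM trains one binary SVM per class pair and decodes by
majority vote; a tied vote (e.g. a three-way cycle) is broken by the
largest aggregate signed margin distance.

`generalization_error` is reported as training accuracy minus the selected
configuration's mean cross-validation accuracy — the overfitting gap. This
is one of several plausible formalizations of that diagnostic; it is
deliberately simple and is computed on the training partition only.

Evaluation reports a 3×3 confusion matrix, per-class accuracy (the
within-class hit rate, identical to recall), one-vs-rest precision/recall/
F1, and macro averages, all on the held-out test partition used once.

## Orchestration

`run_pipeline` executes preprocess → segmentation (×4) → features →
selection (×2) → classifiers (×3) over a manifest, quarantining per-image
failures in `errors.csv` rather than aborting, and writes every
intermediate artifact (masks, Dice CSV, feature CSV, selection JSON/CSV,
report JSON, tuning trace) plus a cross-product summary CSV. Every
stochastic stage draws its seed deterministically from the global seed and
a stage tag, so a rerun with the same inputs reproduces the summary
bit for bit. Single-image inference (`classify_single`) additionally
declares "no plaque detected" when the segmented foreground does not rise
at least 4 robust sigmas above the background median.

## Problem sizes

The validation study uses 150 phantoms per stage (450 images; a 90-image
test partition), Dice evaluation uses 51 phantoms, and the oracle checks
use 1000 random 16×16 images and several hundred random co-occurrence
matrices — sizes at which every Monte-Carlo margin observed is comfortable
while a full run stays in the minutes range on one CPU.

## Known limitations

* The phantom omits optical and biological realism (see above); results on
  phantoms bound what the pipeline can do, not what CARS tissue data will
  yield.
* IFCT is realized from its textual description (seed threshold →
  per-candidate local Otsu → union); other realizations are conceivable.
* Whether real pipelines of this kind measure intensity features on
  enhanced or acquired pixels varies; this package uses acquired pixels,
  for the reason given under Preprocessing.
* GLCM quantization (32 levels) and offset distance (1 px) are package
  conventions; texture values are comparable only within a fixed
  convention.
* Complex lesions (AHA types V/VI), collagen/SHG imaging and deep-learning
  classifiers are out of scope.
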