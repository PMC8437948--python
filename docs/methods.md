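# Methods

## Problem setting

Psoriasis presents as red (erythematous) plaques carrying white keratin
flakes (scale). Clinical severity grading assigns each symptom an integer
0–4 per local lesion image; the grade sum places the image in one of five
groups (healthy 0, mild 1–2, moderate 3–4, severe 5–6, very severe 7–8).
The full-body PASI score additionally weights (erythema + thickness +
scale) by a 0–6 area grade per body region (0.1 head, 0.2 upper
extremities, 0.3 trunk, 0.4 lower extremities; range 0–72). Thickness and
area need 3-D or whole-body information and are out of scope here; the
pipeline assesses erythema and scaling from 2-D local photographs.

## Synthetic scenes

Clinical images cannot be redistributed, so all experiments run on a
generator that emulates their structure while providing exact ground truth.

* **Background** — uniform skin tone in CIE-Lab (default (70, 12, 18)),
  multiplied by a smooth shading ramp along a random direction
  (peak-to-peak amplitude `shadow_amplitude`, default 6 L\* units), with
  `n_hairs` (default 12) thin dark quadratic Bézier strokes.
* **Plaques** — 1–4 blobs obtained by thresholding a radial bump distorted
  by Gaussian-smoothed noise; this reproduces irregular, ambiguous
  boundaries rather than elliptical ones.
* **Erythema** — inside each plaque a\* rises by `erythema_score ×
  erythema_a_gain` (default gain 8) with a radial falloff whose edge band
  widens as the grade drops (1.5·(5 − grade) px), so mild lesions have the
  most ambiguous boundaries; L\* drops slightly with the shift.
* **Scale** — a correlated speckle field (Gaussian-filtered noise,
  correlation length 2.5 px, so flakes are multi-pixel structures) is
  thresholded at the quantile that covers `scale_score ×
  scale_coverage_gain` (default gain 0.12) of the plaque, and rendered
  near-white (high L\*, low chroma).
* **Rendering** — the Lab canvas is blurred (σ = 1 px lens blur) and
  converted to 8-bit sRGB.

Ground-truth masks: the lesion mask is the union of blobs; the scale mask
is the planted speckle set; the erythema mask is defined on the rendered
(post-blur) redness field — lesion pixels retaining at least half the full
a\* shift, minus scale — because the blur moves the visible component
boundary and ground truth should describe what an annotator sees. Healthy
scenes (both grades 0) contain no lesion and have empty masks.

The generator does **not** model body-part geometry, specular highlights,
camera noise, multiple skin-tone populations (the base tone is a single
parameter), or thickness. Passing tests therefore demonstrate that the
algorithms recover structure under controlled color/texture contrast and
realistic nuisance (shading, hairs, blur, ambiguous boundaries); they are
not a clinical-accuracy claim.

## Segmentation

The automatic route over-segments into ~700 SLIC superpixels (local
k-means in [L\*, a\*, b\*, x, y]; compactness 10; 10 SLIC iterations;
connectivity enforced), then runs seeded k-means++ (3 centers, up to 500
iterations) on superpixel mean Lab colors. The quoted 500 iterations are
assigned to this secondary clustering; SLIC itself converges in the
standard 10. The lesion is selected from the cluster map by a rule:

* `max_a` (default) — the cluster with maximum mean a\*;
* `a_above_median` — every cluster whose mean a\* exceeds the image median
  a\* (useful when scale flakes form their own near-white cluster that the
  single reddest cluster would miss);
* `manual` — explicit ids.

Because the argmax always returns something, a redness guard empties the
mask when the chosen cluster's mean a\* exceeds the image median by less
than `redness_margin` (default 2): clusters of healthy skin differ only in
shading L\* (spread < 0.5 in a\*), while even grade-1 erythema sits ~5
above the median. Morphological cleanup fills holes and drops components
under 25 px.

The semi-automatic alternative is a two-phase reaction–diffusion level
set: φ starts as the signed distance of the seed mask; each of 15
iterations takes one explicit step (Δt₁ = 1) of an edge-stopped Chan–Vese
region force (means contrast normalized to unit magnitude, with a weak
curvature term, weight 0.2) and then a diffusion sub-step
φ ← φ + Δt₂·Δφ with Δt₂ = 0.001. On a constant image the region force
vanishes and the initialization is preserved; Δt₂ = 0 reduces to pure
evolution.

## Similarity metrics

DICE, GCE, VoI (bits), Hausdorff distance (pixels) and Rand index are
computed on the 2-region partitions induced by binary masks, all from the
2×2 contingency table except HD (point-set distances). Conventions for two
empty masks: DICE 1, GCE 0, VoI 0, RI 1; HD raises (distance to an empty
set is undefined). GCE uses the global form — the smaller of the two
one-directional refinement-error sums, divided by n; the per-pixel-min
variant (LCE) is not used. Larger DICE/RI and smaller GCE/VoI/HD mean more
similar masks; VoI is 0 for identical partitions.

## Patch decomposition

Lesion pixels are clustered in Lab by seeded k-means (k = 3: erythema /
scale / transitional; k exposed). Cluster→symptom labeling is by color
statistics: maximum mean a\* → erythema, maximum mean L\* among the rest →
scale. Patch images keep the original RGB inside the component and are
black elsewhere. Patches inherit the parent image's grades and are never
geometrically augmented.

## Dataset assembly

Crop rule: aspect ratio ≥ 1.4 → the long axis splits in 3 and the short in
2 (6 crops), otherwise 2×2 (4 crops); integer remainders go to the last
row/column so crops tile exactly. Mode B adds 11 geometric variants per
kept crop: rotations 90/180/270, horizontal flips of the identity and each
rotation, uniform expansion ×1.25, uniform reduction ×0.8, and ×1.25
stretches along x and y (images bilinear, masks nearest-neighbor). Crops
with lesion fraction below 1% are dropped unless the source is healthy.

## Features

All statistics are masked to the lesion (or patch); pixel pairs, runs and
LBP neighborhoods must lie inside the mask. An empty mask (healthy image)
falls back to the whole image — the skin itself is then the region of
interest. Pool sizes are fixed: texture 33, color 27, spectrum 49.

* GLCM: 32 gray levels quantized over the masked range, distance 1, four
  angles, symmetric, angle-averaged contrast/correlation/energy/
  homogeneity/entropy.
* GLRLM: run-length matrices over four directions (runs break at mask
  boundaries); SRE, LRE, GLN, RLN, RP, LGRE, HGRE, direction-averaged.
* Intensity histogram (64 bins over [0, 256)): mean, variance, skewness,
  kurtosis, energy, entropy; skewness/kurtosis defined as 0 for constant
  regions.
* Semi-variogram at lags {1, 2, 4, 8} over horizontal+vertical masked
  pairs, plus the slope over log₂-lag; a lag with no valid pair
  contributes 0 and is excluded from the slope fit.
* Uniform LBP (P = 8, R = 1): normalized 10-bin histogram over interior
  (eroded-mask) pixels.
* Color: mean and SD of all 12 channels of RGB, HSV (H in degrees), Lab
  (sRGB/D65), full-range BT.601 YCbCr, plus a\*/L\* skewness and the
  erythema index mean a\* − mean b\*.
* Gabor: 4 orientations × frequencies {0.1, 0.2, 0.4}; kernels are made
  strictly zero-mean, applied with reflected boundaries via FFT; mean and
  SD of the magnitude response over the mask.
* Zernike: magnitudes |Z_nm| up to radial order 8 (25 values) on the
  mask's bounding circle about its centroid, intensities normalized to
  unit sum. On a pixel lattice, moments with m not divisible by 4 vanish
  exactly for D4-symmetric masks; m = 4, 8 keep small pixelation leakage
  that any discrete implementation shows.

## Feature selection

Three filter rankings: greedy mRMR with the MID criterion (mutual
information on 10 equal-width bins; first pick maximizes I(f; y), later
picks maximize relevance minus mean redundancy against the selected set);
the χ² statistic of the binned-feature × class table (no continuity
correction; degenerate single-bin features score 0); and ReliefF
(range-normalized features, Manhattan distance, every sample an anchor,
k = 10 nearest hits/misses, miss contributions weighted by class priors).
The consensus keeps the top ⌈2p/3⌉ of each ranking and intersects; ties
break by original feature order. An empty intersection is an error.

Selection runs once on the assembled dataset by default;
`cross_validate(select_in_fold=True)` instead reruns the consensus inside
every training fold to avoid selection leakage. Whole-dataset selection is
the default because per-fold ReliefF over 50 folds costs more than the
rest of the pipeline combined, and at the pipeline's effect sizes the two
settings agree; the flag exists for leakage-sensitive analyses.

## Classification and evaluation

Six classifiers (all behind one spec): one-vs-one ECOC over RBF SVMs,
Gaussian naive Bayes, k-NN (k = 5), random forest (100 trees), AdaBoost
over 100 depth-1 stumps, and a 4-layer fully connected network
(256-128-64 hidden units, Adam, learning rate 0.001, batch 32,
cross-entropy, 200 epochs, no early stopping). Features are z-scored
inside each training fold. Evaluation uses stratified 5-fold CV repeated
10 times; each fold's confusion matrix yields overall accuracy,
macro-averaged one-vs-rest sensitivity/specificity/precision/F1, the
generalized multiclass MCC and Cohen's kappa, aggregated as mean ± SD. F1
is the headline metric. Note that for a binary matrix the macro average
differs from the positive-class value; `compute_metrics` returns both the
aggregates and a per-class table.

## Numerical and scale choices

* All randomness flows from explicit integer seeds (scene seeds, k-means
  seeds, CV splits); reruns are byte-identical.
* k-means uses seeded k-means++ with a single initialization, so fixed
  seeds give fixed clusterings.
* The end-to-end experiment in the tests and acceptance script uses 30
  scenes of 256×256 (6 per group), mode B augmentation and texture+color
  features (~1150 dataset rows); this size keeps a full run around a
  minute while leaving every class with dozens of training crops per fold.
* Crops of one scene may land in different CV folds; fold assignment is at
  the crop level, matching the dataset-construction convention, so
  reported F1 measures crop-level generalization, not patient-level.

## Known limitations

* The lesion-selection rule assumes erythema is the dominant color cue;
  pure-scale lesions (erythema grade 0, scale > 0) have no redness and the
  default automatic route returns an empty mask.
* The level-set implementation is single-front two-phase and needs a
  non-empty seed mask; it is not a general multi-region solver.
* Severity labels of crops inherit the parent image's grade even when a
  crop contains only part of the plaque; the lesion-content filter bounds
  but does not eliminate this label noise.
* Synthetic results transfer to clinical images only to the extent the
  generator's nuisance model covers real acquisition conditions.
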