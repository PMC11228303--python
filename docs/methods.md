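# Methods

This note records the modelling choices behind `fusionrad`: what each stage
computes, the defaults and why, what the synthetic phantoms do and do not
emulate, and the numerical conventions. It states no empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## Radiomics features

**Quantization.** Texture matrices are computed on integer gray levels
obtained by equal-width binning of the ROI intensity range into `Ng`
levels (ROI maximum maps to level `Ng`; level 0 marks "outside ROI").
Default `Ng = 32`; the discretization scheme is a package choice, chosen
because equal-width binning over the ROI range makes the texture features
invariant to affine intensity maps — which also lets radiomics run on the
raw (pre-z-score) intensities without loss of generality. A constant ROI
quantizes to level 1 with a warning.

**First-order statistics** operate on the raw ROI intensities: mean,
variance (ddof = 1), min/max, 10th/50th/90th percentiles, histogram energy
and entropy over `Ng` equal-width bins, and the adjusted Fisher–Pearson
sample skewness and excess kurtosis (the ddof = 1 estimators; scipy's
`bias=False`). A closed-form anchor: for the symmetric sample
`{0, 0, 1, 1}` skewness is 0 and kurtosis is exactly −6.

**Gradient features** use numpy's central-difference gradient (one-sided
at borders); the magnitude is the Euclidean norm over spatial axes, and
the same four moments are taken over ROI voxels.

**GLCM** counts ordered level pairs at displacement `d·v` with both
endpoints in the ROI; symmetric mode adds the transpose. Directions:
`(0,1), (−1,1), (−1,0), (−1,−1)` in 2D (0°/45°/90°/135°), the 13 unique
sign-canonical offsets in 3D. Features (contrast, energy/ASM, entropy with
`0·log 0 ≡ 0`, homogeneity) are computed per normalized directional matrix
and arithmetically averaged over the direction set.

**GLRLM** counts maximal same-level runs per direction, truncated at ROI
boundaries (a non-ROI voxel breaks a run). Conservation `Σ L·counts =
|ROI|` holds exactly by construction and is asserted in tests. Features:
SRE, LRE, gray-level / run-length non-uniformity, run fraction
`Nr / |ROI|`, direction-averaged.

**GLSZM** labels connected components of each level with the full
(infinity-norm) structuring element — 8-connected in 2D, 26-connected in
3D — via `scipy.ndimage.label`; features mirror the GLRLM set with run
length replaced by zone size.

**Degenerate values.** Any statistic undefined on its input (skewness of a
constant ROI, kurtosis with n < 4) is imputed as 0 and flagged in the
vector's provenance, keeping the feature vector a fixed length for the
SVM. Extraction is per channel; volumes in `2d` mode average per-slice
features over slices with ≥ 4 ROI voxels, `3d` mode uses the 3D direction
set directly.

## Preprocessing

Foreground is defined as "non-zero in any channel before normalization".
The chain is crop → (optional filter) → z-score → foreground channel:

- **Crop**: minimal bounding box of the foreground, with offsets kept so
  the crop can be inverted exactly.
- **Z-score**: per channel over foreground voxels only, sample sd
  (ddof = 1) with a floor of 1e-8 (constant channels warn); background
  voxels remain exactly 0, and the foreground membership is carried on the
  sample so the zero set is recoverable after shifting.
- **Foreground channel**: a one-hot indicator appended as channel C+1,
  letting the network distinguish "zero because background" from "zero
  because z-scored mean".
- **Filters**: a plain median filter and the soft weighted median (SWMF).
  The SWMF's exact published form is not specified anywhere we could
  follow, so it is defined here explicitly: the output voxel is the
  weighted median of its window with weights
  `softmax(−|x_k − median(window)| / T)`. The temperature `T` (default
  0.1 on z-scored intensities) controls softness; `T → 0` recovers the
  plain median exactly, which is the anchor its tests pin. Padding is
  numpy-style reflect (edge sample not duplicated) for all filters.
- **Resize**: bilinear per-slice resize (default target 256×256); output
  range cannot exceed the input range beyond interpolation tolerance.

The order crop → filter → normalize was chosen so the filter sees raw
intensities; the alternative order is not exposed.

## Augmentation

Seven training-time transforms with fixed probabilities and ranges:
per-axis flips (p = 0.5 each), Gaussian blur (σ ~ U(0.5, 1.5), p = 0.15),
brightness scale (U(0.7, 1.3), p = 0.15), zoom-in (f ~ U(1.0, 1.4),
p = 0.15; central 1/f crop resized back, cubic for image, nearest for
masks, shape always preserved), additive Gaussian noise (variance
~ U(0, 0.33), p = 0.15, interpreted on z-scored intensities), contrast
scale clipped to the original per-channel range (U(0.65, 1.5), p = 0.15),
and a biased patch crop (default (5, 128, 128, 128)) that with p = 0.4 is
drawn uniformly among the windows containing at least one lesion voxel
(computed exactly with a separable window-maximum filter), otherwise
uniformly among all windows. Geometric transforms act congruently on
image, mask and foreground; labels are never touched; all randomness flows
from one `numpy.random.Generator`.

## Network

The CNN is built on a package-internal numpy reverse-mode autodiff engine
(float64, single-threaded, im2col convolutions; the transpose convolution
is implemented as the exact adjoint of the convolution, sharing the
backward-data routine). This keeps the whole artifact installable without
a deep-learning framework and makes training bit-reproducible for a fixed
seed.

**Seq-ResNet block**: 1×1 reduce to 15 channels → split into five
3-channel subspaces F0…F4 → subspace j passes through j factorized
3×1∘1×3 stages (j = 0 untouched; stages beyond a subspace's first are
depthwise-separable with a trailing 1×1 pointwise mix; one BN + ReLU per
stage) → concat → 1×1 restore → add identity. There is deliberately no
activation after the residual addition, so zeroing all conv weights makes
the block the exact identity — a contract the tests assert. At width 64
the block holds ~2.6k parameters versus ~74k for a plain two-3×3-conv
residual block.

**Resampling modules** are back-projection style: project (transpose conv
k2 s2 up, strided conv down), project back, and re-project the
reconstruction residual, merging via concat + 1×1. They contain no
normalization or internal activation (linear modules; with biases disabled
zero input maps to zero output). Downsampling requires even spatial dims.

**FusionNet**: stem 3×3 conv → five stages of Seq-ResNet blocks, default
plan (6, 8, 12, 8, 3) = 37 blocks at widths (32, 64, 96, 96, 64), with a
downsampling module (plus 1×1 width change) between stages → one
upsampling module → global average pooling → FC to `fc_dim` (default 256)
→ FC classification head. The stage layout and `fc_dim` are package
choices (no canonical layout exists for the 37-block depth);
`depth_scale < 1` shrinks every stage's block count (floor 1) for
desk-scale runs with identical topology. Inputs need spatial dims
divisible by 16 (four halvings).

**Training**: Adam (β = 0.9/0.999), lr 1e-4, ≤ 150 epochs, batch 16,
cross-entropy; conv/FC weights ~ N(0, 0.01) (sd 0.1), biases 0, BN γ = 1 /
β = 0. Early stopping with patience 15 on the monitored loss (validation
if provided, else training), restoring the best epoch. The 2D slice
network is the implemented variant; a 3D-conv variant is out of scope for
the numpy engine.

## Fusion and classification

Feature tables are joined strictly on `sample_id` (mismatches raise with
the offending ids). Standardization and every model-selection decision use
training-fold data only; a leakage canary test injects a feature that is
informative only on held-out rows and asserts the inner-CV selection
scores are exactly unchanged.

The multi-kernel SVM scores each candidate on a grid — C ∈ {0.1, 1, 10};
RBF/poly γ ∈ {1/d, 0.01, 0.1}; poly degree ∈ {2, 3}, coef0 = 1 — by inner
stratified 3-fold CV accuracy, refitting the winner on the full training
split. Ties break by kernel order (linear, polynomial, RBF), then smaller
C, implemented by strict-improvement scanning in that candidate order. The
dual optimization is scikit-learn's SVC; a consistency path re-evaluates
the decision function from the dual coefficients through the package's own
kernel functions. Outer evaluation: stratified 5-fold CV; ROC/AP use the
signed decision values (rank-based metrics only need a monotone score).

## Metrics

P, R and F_α = (α²+1)PR/(α²P + R) with the 0/0 convention "0, flagged";
AP integrates the all-points precision envelope over recall increments;
mAP is the arithmetic mean of per-class APs; ROC-AUC is the trapezoidal
area with tied scores collapsed into single threshold steps, which makes
it exactly the rank-averaged Mann–Whitney U normalized by
`n_pos · n_neg` (asserted at 1e-10 against scipy and a pairwise-count
oracle).

## Synthetic phantoms

Each phantom is an elliptical "tissue" foreground (background ring exactly
0, at least the requested background fraction) filled with a Gaussian
random field — white noise convolved with an isotropic Gaussian of
correlation length σ — mapped affinely to an intensity mean/sd, plus one
lesion blob whose interior texture follows class parameters. Benign
lesions use (σ 0.8, mean 1.3, sd 0.25); malignant lesions interpolate
linearly with `separability` toward (σ 3.0, mean 1.9, sd 0.25), i.e.
smoother and brighter at full separability, identical at 0. Tissue is
(σ 1.0, mean 1.0, sd 0.2); lesion radius ~ U(0.15, 0.30)·min(dims). These
values were chosen once to give GLCM-visible texture differences at a few
dozen voxels' scale and were not tuned against test outcomes.

What a green test establishes: the pipeline recovers class structure that
lives in second-order texture and mean intensity, and degrades to chance
when that structure is absent. What it does not establish: performance on
real MRI — phantoms have no anatomy, no bias fields, no multi-class masks,
no inter-scanner variation, and their class signal is far cleaner than
clinical labels.

## Numerical conventions and limitations

- All crops/offsets are 0-based, half-open; arrays are channel-first
  (C, H, W[, D]).
- Everything is float64; the CNN engine is single-threaded and therefore
  slow relative to a GPU framework — depth-scaled configs are the intended
  desk-scale mode, and full-scale (37-block, 256×256) training is not
  practical on one CPU.
- DICOM series reading requires the optional `pydicom` extra; NIfTI (4D
  single-file or per-channel `_000…` set) is the first-class path.
- Weighted-median ties resolve to the smallest value whose cumulative
  weight reaches half the total.
- The per-class feature layout, names and order are fixed and stable
  across runs; degenerate-feature imputation never changes vector length.
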