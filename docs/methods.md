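# Methods

## Problem and approach

Gadolinium contrast-enhancing lesions (CELs) mark acute blood–brain-barrier
breakdown in multiple sclerosis. They are small (down to 3 voxels at 1 mm
isotropic), sparse (most scans in a clinical cohort have none), and easily
confused with physiological post-contrast hyperintensities such as veins.
`celseg` implements a patch-based 3D U-Net pipeline that exploits one
anatomical fact throughout: a CEL is by definition the acute component of a
white matter lesion (WML), so the WML mask constrains where training
patches are sampled, where inference looks, and which predicted components
are plausible.

The pipeline stages, in the order they run:

1. **Inputs.** Per scan: T1-weighted pre- and post-gadolinium, FLAIR, a
   binary WML mask, and (for training) a binary CEL ground-truth mask — all
   co-registered, skull-stripped, 1 mm isotropic NIfTI volumes.
2. **Normalization.** Each channel is z-scored over brain voxels (nonzero
   intensities); background stays 0. Statistics are per volume, never
   pooled across scans or channels.
3. **Patch sampling.** From each scan, `patches_per_scan` (reference: 32)
   crops of `initial_patch_mm`³ (reference: 64³) are taken: for
   CEL-positive scans, round(1/3 · n) centered on CEL voxels and the rest
   on WML voxels; CEL-free scans contribute WML-centered crops only. A
   second random crop reduces each patch to `final_patch_mm`³ (reference:
   48³). Centers are drawn uniformly over mask voxels, so larger lesions
   are sampled proportionally more often. Windows are clamped at grid
   boundaries rather than padded.
4. **Augmentation.** Random axis flips, random 90° rotation of a random
   axis pair, a small random affine (rotations ≤ 10°, isotropic scale
   0.9–1.1, no shear; nearest-neighbour for masks), and a scalar intensity
   shift drawn uniformly from ±0.25 added to the image channels only.
   Augmentation runs after the sub-crop, and every spatial transform is
   applied voxel-identically to channels, ground truth and WML crops.
5. **Network.** A 3D U-Net: encoder filters (32, 64, 128, 256, 512),
   mirrored decoder, stride-2 downsampling between levels, two 3×3×3
   convolutions per level each followed by instance normalization and
   PReLU, nearest-neighbour upsampling, concatenation skip connections,
   and a 1×1×1 sigmoid head producing one probability per voxel. Width and
   depth are configurable; input edges must be divisible by
   stride^(levels−1).
6. **Loss.** Soft dice plus focal loss (γ = 2). The *starting* objective
   is `0.5·mean(dice) + mean(focal)` over the batch. The *weighted*
   objective divides each CEL-free ("negative") patch's dice loss by the
   imbalance rate — the negative:positive patch count ratio, measured on
   the first epoch's patches by default (the reference cohort's value is
   29) — before averaging, and leaves the focal term untouched. A patch is
   *positive* iff its ground-truth crop contains ≥ 1 CEL voxel, regardless
   of where its center was drawn.
7. **Inference.** Deterministic `final_patch_mm`³ windows tile the grid at
   50% overlap; only windows intersecting the WML mask are predicted,
   which still covers every WML voxel. Per-voxel probabilities from
   overlapping windows are averaged and thresholded at 0.5; voxels covered
   by no window are 0.
8. **Postprocessing.** 26-connected components of the binary prediction
   are filtered by a conjunction of two rules: volume ≥ 3 voxels, and
   ≥ 10% of the component's own voxels inside the WML mask (exactly 10%
   is kept). This removes vessel-like confounders, which never overlap the
   WML mask.
9. **Evaluation.** Detection is lesion-wise: TPR = TP/(TP+FN),
   FPR = FP/(TP+FP), where a ground-truth component touched by ≥ 1
   predicted voxel is a TP, a predicted component touching no ground truth
   is an FP, and a predicted component is never an FP if it touches any
   ground-truth lesion (an IoU-threshold mode exists). Segmentation is the
   hard Dice 2TP/(2TP+FN+FP), reported per TP lesion (ground-truth
   component vs the union of predicted components matched to it), per
   whole image (only images with ≥ 1 TP lesion), and per validation patch
   (WML-overlap filtering only — no 3-voxel rule, since patches may clip a
   lesion). TP/FN lesions are stratified by ground-truth volume into bins
   3–10, 10–20, 20–30, 30–40, 40–50, 50–100, 100–200, 200–300, > 300 mm³;
   FPs by their own volume.
10. **Cross-validation.** Patients are partitioned into `n_folds`
    (reference: 11) folds; all scans of a patient share a fold. One fold is
    test, one validation, the rest train. The pipeline itself asserts the
    patient sets of train/validation/test are disjoint. Model selection
    keeps the checkpoint with the highest whole-image validation Dice,
    computed through the full inference + filtering path.

## Design choices where the design was open

- **Direction of the imbalance weight.** The weighted objective is
  motivated as *reducing* the influence of the saturated dice loss on
  negative patches, yet a literal multiply-by-rate formula would do the
  opposite. We implement the intent — the negative dice term is divided by
  the rate — and keep the literal multiply-by-rate behaviour behind
  `LossConfig(eq5_literal=True)`, tested for numerical correctness only.
- **Combination of overlapping inference windows.** Sum-then-clip of
  *binarized* windows is a union: any one of up to eight overlapping
  windows can switch a voxel on, and because instance normalization makes
  window predictions context-dependent, the union inflates small false
  positives badly (measured on the phantom: 6 TP / 45 FP under union vs
  6 TP / 0 FP under averaging, same trained model). The default therefore
  averages per-voxel probabilities before thresholding; the union mode
  remains available as `infer_scan(..., mode="binary")`.
- **Binarization threshold 0.5** (unstated in the source method); the
  sigmoid head makes 0.5 the natural decision boundary.
- **Block composition** (two convs + instance norm per level, nearest
  upsampling, concat skips) follows common 3D U-Net practice; the
  reference description fixes only filter counts, stride and PReLU.
- **Patch-count rounding.** "One of every three" of 32 patches is not an
  integer; we use round(32/3) = 11 CEL-centered patches.
- **Matching criterion.** One shared voxel makes a TP — the weakest
  criterion consistent with lesion-wise counting; stricter IoU matching is
  available as a parameter.
- **WML-overlap denominator.** The 10% rule is read as 10% *of the
  predicted lesion* inside the WML mask; reading it as 10% of the whole
  WML mask would reject nearly every small CEL.

## Numerical details

- Dice smoothing ε = 1e-5 in numerator and denominator; focal-loss
  probabilities clamped to [1e-7, 1−1e-7] before the log.
- He-normal weight initialization; PReLU slopes start at 0.25; Adam with
  β = (0.9, 0.999), ε = 1e-8; reference learning rate 5e-5.
- The network trains in float32 (float64 is available for gradient
  checking; all analytic gradients are verified against central finite
  differences in the test suite).
- All randomness flows through explicit `numpy.random.Generator` objects;
  fixed seeds reproduce runs bit-for-bit, including byte-identical
  NIfTI output (gzip mtime pinned to 0).
- Degenerate inputs: an empty WML mask is a hard error for training
  sampling ("no sampling support") and a warned all-zero prediction at
  inference; a CEL-free validation fold is rejected because the selection
  metric would be undefined; a constant image within the brain mask is a
  z-scoring error.

## The synthetic phantom

The generator emulates the *statistical contract* of a clinical MS cohort,
not its anatomy. Per scan: an ellipsoidal "brain" with piecewise-constant
tissue intensities plus Gaussian noise (σ = 0.15 against a brain mean of
1.0); 8 ellipsoidal WML components of 100–4000 mm³, hyperintense on FLAIR;
with probability 208/372 ≈ 0.56 the scan is CEL-positive and carries
1 + Poisson(2) lesions (mean 3); lesion volumes follow a lognormal
(μ = 4.07, σ = 1.30; mean ≈ 136 mm³) truncated at 3 voxels, carved as
connected blobs strictly inside WML components by distance-ordered region
growing; CELs are hyperintense on post-contrast T1 (2.0 vs 0.95 for
plain WML). Three vessel-like tubes per scan (radius ≈ 1–2 voxels) are
post-contrast-bright but never intersect the WML mask, so they are exactly
the false-positive candidates the WML-overlap filter must remove. An
optional hollow-shell variant mimics ring-enhancing lesions; an optional
linear bias field exists and is off by default.

What the phantom does *not* model: real anatomy and lesion texture, MR
physics, partial-volume effects, bias fields (by default), registration
error, scanner/site variation, or CELs touching the WML border (synthetic
CELs are strict subsets). Passing the end-to-end test therefore
demonstrates that the pipeline's machinery — sampling, loss, training,
reconstruction, filtering, lesion-level scoring — recovers lesions whose
defining intensity relations hold exactly; it does not certify clinical
performance.

## Desk-scale profile

The default configurations carry the reference values (64³→48³ patches,
widths 32–512, lr 5e-5, 11 folds, rate 29). The `demo_profile()` used by
`celseg demo`, the end-to-end test and `scripts/acceptance.py` scales the
problem to a single CPU: 96³ phantom grid, 20 scans from 17 patients,
6 folds, 24³→16³ patches, 12 patches/scan, encoder (4, 8, 16), Adam
lr 3e-3, 50 epochs, validation every 10 epochs. The loss-direction
experiment uses 6 scans, 16 patches each at 12³ with positive fraction
1/16 (an imbalanced set, as in the clinical setting), 60 optimizer steps
per loss, identical initialization and batch order for both losses, and a
majority vote over 3 seeds.

## Known limitations

- The numpy network is CPU-bound and has no GPU path; reference-width
  training at 48³ patches is out of desk scope by design.
- Fold selection for the demo rotates to folds containing at least one
  CEL-positive scan (validation Dice and test TPR are undefined
  otherwise); with 56% positive scans and 3–4-scan folds this triggers
  rarely and is logged in the report.
- Whole-image Dice on the phantom underestimates what the same pipeline
  reports on larger lesions, because small lesions dominate the phantom's
  volume distribution and a one-voxel rim error is a large Dice penalty.
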