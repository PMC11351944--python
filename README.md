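# celseg

Detection and segmentation of gadolinium **contrast-enhancing lesions
(CELs)** in multiple sclerosis MRI, guided by white-matter-lesion (WML)
masks.

CELs mark acute inflammatory activity with blood–brain-barrier breakdown
and drive both MS diagnosis and treatment monitoring, but they are tedious
to annotate by hand: small (down to 3 voxels ≈ 3 mm³ at 1 mm isotropic),
sparse (most clinical scans have none), and easy to confuse with
physiological post-contrast hyperintensities such as veins. `celseg` is a
patch-based 3D U-Net pipeline for this task, built around the anatomical
fact that a CEL is the acute component *within* a white matter lesion: the
WML mask steers patch sampling during training, restricts inference to
plausible regions, and filters implausible predictions afterwards.

The package is aimed at neuroimaging methods researchers. Because clinical
cohorts with consensus CEL annotations are not freely shareable, it ships
a synthetic multi-contrast phantom generator that reproduces the
*statistical* structure of such a cohort (positive-scan fraction ≈ 0.56,
mean 3 CELs per positive scan, lognormal lesion volumes with mean
≈ 136 mm³ truncated at 3 voxels, vessel-like confounders outside the WML
mask), so the entire pipeline is runnable and testable without any
patient data.

## Method at a glance

- **Inputs** per scan: T1w pre-gadolinium, T1w post-gadolinium, FLAIR, a
  binary WML mask (and a CEL ground-truth mask for training) — NIfTI,
  co-registered, skull-stripped, 1 mm isotropic.
- **Sampling**: z-score normalization per volume; 32 crops of 64³ per
  scan, one in three centered on CEL voxels (round(32/3) = 11) and the
  rest on WML voxels; random 48³ sub-crop; flips / 90° rotations / small
  affine / ±0.25 intensity-shift augmentation.
- **Network**: 3D U-Net, encoder filters (32, 64, 128, 256, 512), mirrored
  decoder, stride 2, instance norm + PReLU, sigmoid head. Implemented on a
  small numpy reverse-mode autodiff core (`celseg.nn`) with
  finite-difference-verified gradients; width/depth are configurable down
  to CPU-friendly sizes.
- **Loss**: soft dice + focal (γ=2). The *starting* loss is
  `0.5·Dice + Focal`; the *weighted* loss divides the dice term of
  lesion-free patches by the negative:positive patch ratio
  (`rate_imbalance`, 29 in the reference cohort, measured from data by
  default), so training attends to segmenting lesions rather than to the
  saturated dice of empty patches. Lesion-wise detection:
  `TPR = TP/(TP+FN)`, `FPR = FP/(TP+FP)`; segmentation:
  `DSC = 2TP/(2TP+FN+FP)` on voxels.
- **Inference**: 48³ windows tile the WML mask at 50% overlap; per-voxel
  probabilities of overlapping windows are averaged and thresholded.
- **Postprocessing**: 26-connected components; drop components < 3 voxels
  or with < 10% of their voxels inside the WML mask (exactly 10% is
  kept) — this removes vessel-like confounders.
- **Validation**: patient-level cross-validation (all scans of a patient
  share a fold), model selection by whole-image validation DSC.

See `docs/methods.md` for assumptions, parameter tables, numerical
details, and what the phantom does and does not emulate.

## Worked example

Train and evaluate the desk-scale demo — a tiny-width network on a
20-scan synthetic cohort (13 train / 4 validation / 3 test scans after
patient-level fold assignment), 24³→16³ patches, 50 epochs on one CPU
(~11 minutes):

```bash
celseg demo --seed 0 --out demo_run
```

prints, at the end (seed 0):

```json
{
  "n_tp": 6,
  "n_fp": 0,
  "n_fn": 0,
  "tpr": 1.0,
  "fpr": 0.0,
  "mean_lesion_dsc": 0.974,
  "mean_whole_image_dsc": 0.978,
  "n_train": 13,
  "n_val": 4,
  "n_test": 3,
  "best_val_dsc": 0.952,
  "seed": 0
}
```

Reading: the 3 held-out test scans contained 6 true CELs; all 6 were
detected (TPR 1.0) with no surviving false-positive component (FPR 0.0) —
in particular, none of the vessel-like confounder tubes survives the
WML-overlap filter. Each detected lesion overlaps its ground truth at
Dice 0.97 on average, and whole-image Dice (images with ≥ 1 TP lesion)
is 0.98. `demo_run/` additionally contains the cohort manifest, the
per-epoch training history, and a volume-stratified lesion report
(`volume_strata.csv`) binning TP/FN by ground-truth lesion volume and FP
by their own volume.

Other entry points: `celseg generate` (write a synthetic cohort as NIfTI +
manifest), `celseg train` (YAML-configured run, `--compare-losses` for a
starting-vs-weighted table), `celseg infer`, `celseg postprocess`,
`celseg evaluate`. The same functionality is available as a library
(`celseg.generate_cohort`, `celseg.train_fold`, `celseg.infer_scan`,
`celseg.filter_lesions`, `celseg.match_lesions`, ...).

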