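"""Lesion-level detection and voxel-level segmentation metrics.

Detection is counted over connected lesion components, not voxels:

* TPR = TP / (TP + FN) — the fraction of ground-truth lesions the model
  found;
* FPR = FP / (TP + FP) — the fraction of predicted lesions that are
  spurious (note the denominator: predicted, not negative, lesions).

A ground-truth component touched by at least one predicted voxel is a TP
(one-voxel-overlap matching, the weakest criterion; an IoU threshold is
available). A predicted component overlapping any ground-truth component
is never an FP; a predicted component touching several ground-truth
lesions makes each of them a TP.

Segmentation quality is the Dice score 2·TP/(2·TP+FN+FP) over voxels,
reported per TP lesion (against the union of the predicted components
matched to it), per whole image (only for images with at least one TP
lesion), and per validation patch (where lesions outside the WML are
dropped but no minimum-size rule applies, since a patch may clip a lesion).
TP/FN lesions are stratified by ground-truth volume; FP lesions by their
own volume.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .postprocess import LesionComponent, LesionSet, label_components

__all__ = [
    "DetectionCounts",
    "LesionMatchResult",
    "VolumeStratum",
    "VOLUME_BINS",
    "match_lesions",
    "true_positive_rate",
    "false_positive_rate",
    "dice_coefficient",
    "whole_image_dsc",
    "patch_dsc",
    "stratify_by_volume",
    "strata_table",
]

# lesion-volume strata bounds in mm^3, half-open [lo, hi)
VOLUME_BINS = (
    (3.0, 10.0),
    (10.0, 20.0),
    (20.0, 30.0),
    (30.0, 40.0),
    (40.0, 50.0),
    (50.0, 100.0),
    (100.0, 200.0),
    (200.0, 300.0),
    (300.0, float("inf")),
)


@dataclass
class DetectionCounts:
    n_tp: int = 0
    n_fp: int = 0
    n_fn: int = 0

    def __post_init__(self):
        if min(self.n_tp, self.n_fp, self.n_fn) < 0:
            raise ValueError("lesion counts must be >= 0")

    def __add__(self, other):
        return DetectionCounts(
            self.n_tp + other.n_tp, self.n_fp + other.n_fp, self.n_fn + other.n_fn
        )


@dataclass
class LesionMatchResult:
    counts: DetectionCounts
    tp_pairs: list = field(default_factory=list)   # (gt comp, [pred comps], DSC)
    fp_components: list = field(default_factory=list)
    fn_components: list = field(default_factory=list)


def true_positive_rate(counts: DetectionCounts) -> float:
    """TP / (TP + FN); NaN when no ground-truth lesion exists."""
    denom = counts.n_tp + counts.n_fn
    return counts.n_tp / denom if denom else float("nan")


def false_positive_rate(counts: DetectionCounts) -> float:
    """FP / (TP + FP); NaN when nothing was predicted or matched."""
    denom = counts.n_tp + counts.n_fp
    return counts.n_fp / denom if denom else float("nan")


def dice_coefficient(pred: np.ndarray, gt: np.ndarray) -> float:
    """Hard-mask Dice 2·TP/(2·TP+FN+FP); NaN when both masks are empty."""
    pred = np.asarray(pred, dtype=bool)
    gt = np.asarray(gt, dtype=bool)
    if pred.shape != gt.shape:
        raise ValueError("pred and gt grids differ")
    tp = int((pred & gt).sum())
    fp = int((pred & ~gt).sum())
    fn = int((~pred & gt).sum())
    denom = 2 * tp + fn + fp
    return 2 * tp / denom if denom else float("nan")


def _component_mask(comp: LesionComponent, shape) -> np.ndarray:
    m = np.zeros(shape, dtype=bool)
    m[tuple(comp.voxels.T)] = True
    return m


def match_lesions(
    pred: LesionSet, gt: LesionSet, iou_threshold: float = 0.0
) -> LesionMatchResult:
    """Match predicted to ground-truth components by voxel overlap.

    With the default ``iou_threshold=0`` any shared voxel is a match;
    a positive threshold additionally requires IoU > threshold between the
    gt component and the union of predicted components overlapping it.
    """
    if pred.grid_shape != gt.grid_shape:
        raise ValueError("lesion sets live on different grids")
    shape = gt.grid_shape
    pred_label = np.zeros(shape, dtype=np.int32)
    for c in pred.components:
        pred_label[tuple(c.voxels.T)] = c.label_id
    by_id = {c.label_id: c for c in pred.components}

    result = LesionMatchResult(DetectionCounts())
    matched_pred: set[int] = set()
    for g in gt.components:
        ids = np.unique(pred_label[tuple(g.voxels.T)])
        ids = ids[ids > 0]
        if len(ids) == 0:
            result.fn_components.append(g)
            continue
        preds = [by_id[i] for i in ids]
        gmask = _component_mask(g, shape)
        pmask = np.zeros(shape, dtype=bool)
        for p in preds:
            pmask[tuple(p.voxels.T)] = True
        inter = int((gmask & pmask).sum())
        union = int((gmask | pmask).sum())
        if iou_threshold > 0 and inter / union <= iou_threshold:
            result.fn_components.append(g)
            continue
        matched_pred.update(int(i) for i in ids)
        result.tp_pairs.append((g, preds, dice_coefficient(pmask, gmask)))
    for p in pred.components:
        if p.label_id not in matched_pred:
            # overlap with ANY gt voxel shields a prediction from being FP
            gt_hit = any(
                len(np.intersect1d(_flat(p.voxels, shape), _flat(g.voxels, shape)))
                for g in gt.components
            )
            if not gt_hit:
                result.fp_components.append(p)
    result.counts = DetectionCounts(
        n_tp=len(result.tp_pairs),
        n_fp=len(result.fp_components),
        n_fn=len(result.fn_components),
    )
    return result


def _flat(voxels: np.ndarray, shape) -> np.ndarray:
    return np.ravel_multi_index(tuple(voxels.T), shape)


def whole_image_dsc(pred: LesionSet, gt: LesionSet) -> float:
    """Whole-image Dice of the (filtered) prediction vs ground truth,
    defined only for images with at least one TP lesion (NaN otherwise)."""
    match = match_lesions(pred, gt)
    if match.counts.n_tp == 0:
        return float("nan")
    return dice_coefficient(pred.to_mask(), gt.to_mask())


def patch_dsc(pred_patches, gt_patches, wml_patches) -> float:
    """Mean Dice over qualifying validation patches.

    Within each patch, predicted lesions with zero WML overlap are dropped
    (no minimum-size rule: a patch may contain only a fragment of a CEL);
    the patch qualifies if a TP lesion remains, and the mean is taken over
    qualifying patches only.
    """
    scores = []
    for p, g, w in zip(pred_patches, gt_patches, wml_patches):
        pred_set = label_components(np.asarray(p, dtype=np.uint8))
        kept = [
            c
            for c in pred_set.components
            if np.asarray(w, dtype=bool)[tuple(c.voxels.T)].any()
        ]
        pred_set = LesionSet(kept, pred_set.grid_shape, pred_set.voxel_size_mm)
        gt_set = label_components(np.asarray(g, dtype=np.uint8))
        if match_lesions(pred_set, gt_set).counts.n_tp == 0:
            continue
        scores.append(dice_coefficient(pred_set.to_mask(), gt_set.to_mask()))
    return float(np.mean(scores)) if scores else float("nan")


@dataclass
class VolumeStratum:
    label: str
    lo: float
    hi: float
    n_tp: int
    n_fn: int
    n_fp: int
    mean_dsc: float


def _bin_index(volume: float) -> int:
    for i, (lo, hi) in enumerate(VOLUME_BINS):
        if lo <= volume < hi:
            return i
    return 0  # sub-minimum volumes (filtered upstream) fall into the first bin


def stratify_by_volume(match: LesionMatchResult) -> list:
    """Volume-stratified detection/segmentation report plus an all-volumes
    row. TP/FN are binned by ground-truth lesion volume, FP by their own."""
    n = len(VOLUME_BINS)
    tp = np.zeros(n, dtype=int)
    fn = np.zeros(n, dtype=int)
    fp = np.zeros(n, dtype=int)
    dscs: list[list[float]] = [[] for _ in range(n)]
    for g, _, d in match.tp_pairs:
        i = _bin_index(g.volume_mm3)
        tp[i] += 1
        dscs[i].append(d)
    for g in match.fn_components:
        fn[_bin_index(g.volume_mm3)] += 1
    for p in match.fp_components:
        fp[_bin_index(p.volume_mm3)] += 1
    strata = []
    for i, (lo, hi) in enumerate(VOLUME_BINS):
        label = f"{lo:g}-{hi:g}" if np.isfinite(hi) else f">{lo:g}"
        strata.append(
            VolumeStratum(
                label=label,
                lo=lo,
                hi=hi,
                n_tp=int(tp[i]),
                n_fn=int(fn[i]),
                n_fp=int(fp[i]),
                mean_dsc=float(np.mean(dscs[i])) if dscs[i] else float("nan"),
            )
        )
    all_dscs = [d for _, _, d in match.tp_pairs]
    strata.append(
        VolumeStratum(
            label="All",
            lo=VOLUME_BINS[0][0],
            hi=float("inf"),
            n_tp=int(tp.sum()),
            n_fn=int(fn.sum()),
            n_fp=int(fp.sum()),
            mean_dsc=float(np.mean(all_dscs)) if all_dscs else float("nan"),
        )
    )
    return strata


def strata_table(strata) -> pd.DataFrame:
    """Report table with 2-decimal Dice, mirroring the standard layout."""
    return pd.DataFrame(
        {
            "lesion_volume_mm3": [s.label for s in strata],
            "n_tp": [s.n_tp for s in strata],
            "n_fn": [s.n_fn for s in strata],
            "n_fp": [s.n_fp for s in strata],
            "mean_dsc": [round(s.mean_dsc, 2) if np.isfinite(s.mean_dsc) else np.nan
                         for s in strata],
        }
    )
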