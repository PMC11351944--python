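"""Lesion-level detection metrics, Dice conventions and volume strata,
checked against integer arithmetic and exhaustive-overlap oracles."""

import numpy as np
import pytest

from celseg import (
    DetectionCounts,
    VOLUME_BINS,
    dice_coefficient,
    false_positive_rate,
    label_components,
    match_lesions,
    patch_dsc,
    stratify_by_volume,
    true_positive_rate,
    whole_image_dsc,
)
from celseg.metrics import strata_table

RNG = np.random.default_rng(31)


# ---- rates ---------------------------------------------------------------


def test_detection_rates_on_reference_counts():
    # 56 TP, 4 FN, 1 FP: TPR 56/60 = 0.93, FPR 1/57 = 0.02 (2 d.p.)
    counts = DetectionCounts(n_tp=56, n_fp=1, n_fn=4)
    assert round(true_positive_rate(counts), 2) == 0.93
    assert round(false_positive_rate(counts), 2) == 0.02


@pytest.mark.parametrize(
    "counts,tpr,fpr",
    [
        (DetectionCounts(0, 0, 5), 0.0, float("nan")),
        (DetectionCounts(7, 0, 0), 1.0, 0.0),
        (DetectionCounts(40, 6, 0), 1.0, 6 / 46),
        (DetectionCounts(5, 0, 3), 5 / 8, 0.0),
    ],
)
def test_rate_arithmetic(counts, tpr, fpr):
    got_tpr, got_fpr = true_positive_rate(counts), false_positive_rate(counts)
    assert got_tpr == pytest.approx(tpr)
    if np.isnan(fpr):
        assert np.isnan(got_fpr)
    else:
        assert got_fpr == pytest.approx(fpr)


def test_negative_counts_rejected():
    with pytest.raises(ValueError):
        DetectionCounts(-1, 0, 0)


# ---- dice ----------------------------------------------------------------


def test_dice_identity_disjoint_and_hand_value():
    a = (RNG.random((6, 6, 6)) > 0.6).astype(np.uint8)
    a[0, 0, 0] = 1
    assert dice_coefficient(a, a) == 1.0
    b = np.zeros_like(a)
    b[5, 5, 5] = 1
    a2 = np.zeros_like(a)
    a2[0, 0, 0] = 1
    assert dice_coefficient(a2, b) == 0.0
    # |pred|=4, |gt|=2, overlap 2 -> 2*2/(2*2+0+2) = 2/3
    pred = np.zeros((4, 4, 4))
    gt = np.zeros((4, 4, 4))
    pred.flat[:4] = 1
    gt.flat[:2] = 1
    assert dice_coefficient(pred, gt) == pytest.approx(2 / 3)
    assert np.isnan(dice_coefficient(np.zeros((2, 2, 2)), np.zeros((2, 2, 2))))


def test_dice_matches_integer_oracle_on_random_masks():
    for _ in range(50):
        pred = RNG.random((8, 8, 8)) > 0.6
        gt = RNG.random((8, 8, 8)) > 0.6
        if not (pred.any() or gt.any()):
            continue
        tp = fp = fn = 0
        for p, g in zip(pred.ravel(), gt.ravel()):
            tp += p and g
            fp += p and not g
            fn += g and not p
        expected = 2 * tp / (2 * tp + fn + fp) if (2 * tp + fn + fp) else float("nan")
        assert dice_coefficient(pred, gt) == pytest.approx(expected, nan_ok=True)


# ---- matching ------------------------------------------------------------


def test_exact_prediction_matches_all_components():
    mask = np.zeros((12, 12, 12), np.uint8)
    for i in range(5):
        mask[2 * i, 2 * i, 2 * i] = 1
    res = match_lesions(label_components(mask, connectivity=6), label_components(mask, connectivity=6))
    assert (res.counts.n_tp, res.counts.n_fp, res.counts.n_fn) == (5, 0, 0)
    assert all(d == 1.0 for _, _, d in res.tp_pairs)


def test_empty_prediction_all_false_negatives():
    gt = np.zeros((10, 10, 10), np.uint8)
    gt[0, 0, 0] = gt[4, 4, 4] = gt[8, 8, 8] = 1
    res = match_lesions(label_components(np.zeros_like(gt)), label_components(gt))
    assert (res.counts.n_tp, res.counts.n_fp, res.counts.n_fn) == (0, 0, 3)


def test_matching_agrees_with_pairwise_overlap_oracle():
    for seed in range(100):
        rng = np.random.default_rng(seed)
        pred = (rng.random((10, 10, 10)) > 0.85).astype(np.uint8)
        gt = (rng.random((10, 10, 10)) > 0.85).astype(np.uint8)
        ps, gs = label_components(pred), label_components(gt)
        res = match_lesions(ps, gs)
        # oracle: exhaustive pairwise voxel-set intersections
        pred_sets = [set(map(tuple, c.voxels)) for c in ps.components]
        gt_sets = [set(map(tuple, c.voxels)) for c in gs.components]
        tp = sum(1 for g in gt_sets if any(g & p for p in pred_sets))
        fn = len(gt_sets) - tp
        fp = sum(1 for p in pred_sets if not any(p & g for g in gt_sets))
        assert (res.counts.n_tp, res.counts.n_fn, res.counts.n_fp) == (tp, fn, fp)


def test_one_prediction_spanning_two_gt_lesions_counts_two_tp_zero_fp():
    gt = np.zeros((5, 9, 5), np.uint8)
    gt[2, 1:3, 2] = 1
    gt[2, 6:8, 2] = 1
    pred = np.zeros_like(gt)
    pred[2, 0:9, 2] = 1  # one bar covering both lesions
    res = match_lesions(label_components(pred), label_components(gt))
    assert (res.counts.n_tp, res.counts.n_fp, res.counts.n_fn) == (2, 0, 0)


def test_iou_threshold_mode_demotes_weak_overlaps():
    gt = np.zeros((6, 6, 6), np.uint8)
    gt[0:3, 0:3, 0] = 1  # 9 voxels
    pred = np.zeros_like(gt)
    pred[0, 0, 0] = 1  # IoU 1/9
    loose = match_lesions(label_components(pred), label_components(gt))
    strict = match_lesions(label_components(pred), label_components(gt), iou_threshold=0.5)
    assert loose.counts.n_tp == 1
    assert strict.counts.n_tp == 0 and strict.counts.n_fn == 1


def test_monotonicity_of_rates():
    base = DetectionCounts(5, 2, 3)
    more_tp = DetectionCounts(6, 2, 2)  # one more lesion found
    assert true_positive_rate(more_tp) > true_positive_rate(base)
    more_fp = DetectionCounts(5, 3, 3)  # one more spurious component
    assert false_positive_rate(more_fp) > false_positive_rate(base)


# ---- whole-image and patch DSC conventions -------------------------------


def test_whole_image_dsc_requires_a_tp_lesion():
    gt = np.zeros((8, 8, 8), np.uint8)
    gt[2:4, 2:4, 2:4] = 1
    pred = np.zeros_like(gt)
    pred[6, 6, 6] = 1  # no overlap: zero TP -> excluded, not scored 0
    assert np.isnan(whole_image_dsc(label_components(pred), label_components(gt)))
    assert whole_image_dsc(label_components(gt), label_components(gt)) == 1.0


def test_cohort_mean_excludes_no_tp_images():
    gt = np.zeros((8, 8, 8), np.uint8)
    gt[2:4, 2:4, 2:4] = 1
    good = whole_image_dsc(label_components(gt), label_components(gt))
    miss = whole_image_dsc(label_components(np.zeros_like(gt)), label_components(gt))
    scores = np.array([good, miss])
    assert np.nanmean(scores) == 1.0  # the filtered-loop convention


def test_patch_dsc_keeps_subminimum_fragments_and_filters_non_wml():
    # a 2-voxel lesion fragment IS included (no 3-voxel rule inside patches)
    gt = np.zeros((6, 6, 6), np.uint8)
    gt[1, 1, 1:3] = 1
    pred = gt.copy()
    wml = np.ones_like(gt)
    assert patch_dsc([pred], [gt], [wml]) == 1.0
    # a predicted lesion with zero WML overlap is deleted inside the patch
    pred2 = gt.copy()
    pred2[5, 5, 5] = 1
    wml2 = np.ones_like(gt)
    wml2[5, 5, 5] = 0
    assert patch_dsc([pred2], [gt], [wml2]) == 1.0
    # patches without TP lesions do not qualify
    assert np.isnan(patch_dsc([np.zeros_like(gt)], [gt], [wml]))
    # mean over qualifying patches vs a loop oracle
    score = patch_dsc([pred, pred2, np.zeros_like(gt)], [gt, gt, gt], [wml, wml2, wml])
    assert score == pytest.approx(1.0)


# ---- strata --------------------------------------------------------------


def _synthetic_match(volumes_tp, volumes_fn, volumes_fp):
    """Build a LesionMatchResult with given per-lesion volumes on one grid."""
    from celseg.postprocess import LesionComponent
    from celseg.metrics import LesionMatchResult

    def comp(i, vol):
        return LesionComponent(i, np.zeros((int(vol), 3), int), float(vol))

    tp_pairs = [(comp(i, v), [comp(100 + i, v)], 0.8) for i, v in enumerate(volumes_tp)]
    fns = [comp(200 + i, v) for i, v in enumerate(volumes_fn)]
    fps = [comp(300 + i, v) for i, v in enumerate(volumes_fp)]
    return LesionMatchResult(
        DetectionCounts(len(tp_pairs), len(fps), len(fns)), tp_pairs, fps, fns
    )


def test_strata_binning_and_conservation():
    match = _synthetic_match(
        volumes_tp=[7, 15, 55, 150, 400], volumes_fn=[4, 25], volumes_fp=[9, 350]
    )
    strata = stratify_by_volume(match)
    assert strata[-1].label == "All"
    assert strata[-1].n_tp == 5 and strata[-1].n_fn == 2 and strata[-1].n_fp == 2
    # per-bin totals conserve the all-row
    assert sum(s.n_tp for s in strata[:-1]) == 5
    assert sum(s.n_fn for s in strata[:-1]) == 2
    assert sum(s.n_fp for s in strata[:-1]) == 2
    # a 7 mm^3 TP lands in the 3-10 bin; FP binned by its own volume
    assert strata[0].n_tp == 1 and strata[0].n_fn == 1 and strata[0].n_fp == 1
    assert strata[-2].n_fp == 1  # the 350 mm^3 FP in >300
    table = strata_table(strata)
    assert list(table.columns) == ["lesion_volume_mm3", "n_tp", "n_fn", "n_fp", "mean_dsc"]
    assert table.iloc[-1]["mean_dsc"] == pytest.approx(0.8)


def test_bins_partition_from_three_upward():
    lows = [lo for lo, _ in VOLUME_BINS]
    highs = [hi for _, hi in VOLUME_BINS]
    assert lows[0] == 3.0 and np.isinf(highs[-1])
    assert lows[1:] == highs[:-1]  # contiguous half-open bins
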