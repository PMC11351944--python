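"""Normalization and the two-stage patch sampling: statistics, geometry,
label consistency, and augmentation alignment."""

import numpy as np
import pytest
from scipy import stats

from celseg import (
    Patch,
    SamplingConfig,
    augment,
    extract_patch,
    random_subcrop,
    sample_patch_centers,
    zscore_normalize,
)
from celseg.sampling import normalize_bundle

RNG = np.random.default_rng(23)


# ---- z-score normalization ----------------------------------------------


def test_two_point_standardization():
    vol = np.zeros((2, 2, 2))
    vol.flat[:2] = [1.0, 3.0]
    mask = np.zeros((2, 2, 2), bool)
    mask.flat[:2] = True
    out = zscore_normalize(vol, mask)
    np.testing.assert_allclose(sorted(out[mask]), [-1.0, 1.0])
    assert (out[~mask] == 0).all()


def test_normalization_is_idempotent():
    vol = RNG.normal(2.0, 3.0, size=(8, 8, 8))
    mask = RNG.random((8, 8, 8)) > 0.3
    once = zscore_normalize(vol, mask)
    twice = zscore_normalize(once, mask)
    np.testing.assert_allclose(once, twice, atol=1e-10)


def test_normalization_matches_one_pass_oracle():
    vol = RNG.normal(5.0, 2.5, size=(10, 10, 10))
    mask = RNG.random((10, 10, 10)) > 0.4
    out = zscore_normalize(vol, mask)
    # independent single-pass accumulation
    s = n = ss = 0.0
    for v, m in zip(vol.ravel(), mask.ravel()):
        if m:
            s += v
            ss += v * v
            n += 1
    mean = s / n
    sd = np.sqrt(ss / n - mean**2)
    np.testing.assert_allclose(out[mask], (vol[mask] - mean) / sd, atol=1e-6)
    # moments over the mask
    assert out[mask].mean() == pytest.approx(0.0, abs=1e-6)
    assert out[mask].std() == pytest.approx(1.0, abs=1e-6)


def test_normalization_errors():
    with pytest.raises(ValueError, match="zero variance"):
        zscore_normalize(np.ones((3, 3, 3)), np.ones((3, 3, 3), bool))
    with pytest.raises(ValueError, match="2 voxels"):
        zscore_normalize(np.ones((3, 3, 3)), np.zeros((3, 3, 3), bool))


def test_normalize_bundle_per_channel_statistics(positive_bundle):
    nb = normalize_bundle(positive_bundle)
    brain = positive_bundle.t1_pre != 0
    for vol in (nb.t1_pre, nb.t1_post, nb.flair):
        assert vol[brain].mean() == pytest.approx(0.0, abs=1e-6)
        assert vol[brain].std() == pytest.approx(1.0, abs=1e-6)
        assert (vol[~brain] == 0).all()


# ---- center sampling -----------------------------------------------------


def test_positive_scan_center_split_with_reference_defaults(positive_bundle):
    # 32 patches, one in three on CELs -> round(32/3) = 11 CEL-centered
    cfg = SamplingConfig()
    centers = sample_patch_centers(positive_bundle, cfg, np.random.default_rng(0))
    kinds = [k for _, k in centers]
    assert len(centers) == 32
    assert kinds.count("cel_centered") == 11
    assert kinds.count("wml_centered") == 21


def test_negative_scan_all_wml_centered(negative_bundle):
    centers = sample_patch_centers(
        negative_bundle, SamplingConfig(), np.random.default_rng(0)
    )
    assert len(centers) == 32
    assert all(k == "wml_centered" for _, k in centers)


def test_centers_lie_on_their_claimed_masks(positive_bundle):
    centers = sample_patch_centers(
        positive_bundle, SamplingConfig(), np.random.default_rng(1)
    )
    for c, kind in centers:
        mask = positive_bundle.cel_mask if kind == "cel_centered" else positive_bundle.wml_mask
        assert mask[c] == 1


def test_single_voxel_wml_support(positive_bundle):
    from celseg import ScanBundle

    shape = (70, 70, 70)
    wml = np.zeros(shape, np.uint8)
    wml[35, 35, 35] = 1
    vol = RNG.normal(size=shape)
    b = ScanBundle(vol, vol, vol, wml, np.zeros(shape, np.uint8), "P", "S")
    centers = sample_patch_centers(b, SamplingConfig(patches_per_scan=5), np.random.default_rng(0))
    assert all(c == (35, 35, 35) for c, _ in centers)
    b_empty = ScanBundle(vol, vol, vol, np.zeros(shape, np.uint8),
                         np.zeros(shape, np.uint8), "P", "S")
    with pytest.raises(ValueError, match="no sampling support"):
        sample_patch_centers(b_empty, SamplingConfig(), np.random.default_rng(0))


# ---- cropping ------------------------------------------------------------


def test_extract_origin_arithmetic_and_clamping(positive_bundle):
    cfg = SamplingConfig()  # initial edge 64 on the 96^3 grid
    p = extract_patch(positive_bundle, (48, 48, 48), cfg)
    assert p.origin == (16, 16, 16)
    assert p.gt.shape == (64, 64, 64)
    corner = extract_patch(positive_bundle, (0, 0, 0), cfg)
    assert corner.origin == (0, 0, 0)
    far = extract_patch(positive_bundle, (95, 95, 95), cfg)
    assert far.origin == (32, 32, 32)


def test_extract_roundtrip_reproduces_source(positive_bundle):
    cfg = SamplingConfig(initial_patch_mm=24, final_patch_mm=16)
    p = extract_patch(positive_bundle, (40, 50, 60), cfg)
    sl = tuple(slice(o, o + 24) for o in p.origin)
    np.testing.assert_array_equal(p.gt, positive_bundle.cel_mask[sl])
    np.testing.assert_array_equal(p.wml, positive_bundle.wml_mask[sl])
    np.testing.assert_array_equal(p.channels[1], positive_bundle.t1_post[sl])


def test_subcrop_identity_when_sizes_equal(positive_bundle):
    cfg = SamplingConfig(initial_patch_mm=24, final_patch_mm=24)
    p = extract_patch(positive_bundle, (48, 48, 48), cfg)
    q = random_subcrop(p, cfg, np.random.default_rng(0))
    assert q.origin == p.origin
    np.testing.assert_array_equal(q.gt, p.gt)


def test_subcrop_offsets_uniform_chi_square():
    """Offsets over many draws are uniform on {0..initial-final}^3."""
    cfg = SamplingConfig(initial_patch_mm=6, final_patch_mm=2, patches_per_scan=1)
    base = Patch(
        channels=RNG.normal(size=(3, 6, 6, 6)),
        gt=np.zeros((6, 6, 6), np.uint8),
        wml=np.ones((6, 6, 6), np.uint8),
        origin=(0, 0, 0),
        center_kind="wml_centered",
        is_positive=False,
    )
    rng = np.random.default_rng(99)
    counts = np.zeros(5)
    n_draws = 10_000
    for _ in range(n_draws):
        q = random_subcrop(base, cfg, rng)
        counts[q.origin[0]] += 1
    p = stats.chisquare(counts).pvalue
    assert p > 0.001


def test_subcrop_label_flips_when_lesion_excluded(positive_bundle):
    cfg = SamplingConfig(initial_patch_mm=6, final_patch_mm=2)
    gt = np.zeros((6, 6, 6), np.uint8)
    gt[5, 5, 5] = 1  # lesion voxel only in the far corner
    base = Patch(
        channels=np.zeros((3, 6, 6, 6)),
        gt=gt,
        wml=np.ones((6, 6, 6), np.uint8),
        origin=(0, 0, 0),
        center_kind="cel_centered",
        is_positive=True,
    )
    rng = np.random.default_rng(0)
    seen_negative = False
    for _ in range(50):
        q = random_subcrop(base, cfg, rng)
        assert q.is_positive == bool(q.gt.any())
        seen_negative |= not q.is_positive
    assert seen_negative


# ---- augmentation --------------------------------------------------------


def _toy_patch(edge=8):
    gt = np.zeros((edge,) * 3, np.uint8)
    gt[2:4, 3:5, 4:6] = 1
    return Patch(
        channels=RNG.normal(size=(3, edge, edge, edge)),
        gt=gt,
        wml=np.ones((edge,) * 3, np.uint8),
        origin=(0, 0, 0),
        center_kind="cel_centered",
        is_positive=True,
    )


def test_augment_disabled_is_identity():
    cfg = SamplingConfig(
        enable_flip=False, enable_rot90=False, enable_affine=False, intensity_shift=0.0
    )
    p = _toy_patch()
    q = augment(p, np.random.default_rng(0), cfg)
    np.testing.assert_array_equal(q.channels, p.channels)
    np.testing.assert_array_equal(q.gt, p.gt)


def test_augment_masks_stay_binary_and_labels_consistent():
    cfg = SamplingConfig()
    for seed in range(100):
        q = augment(_toy_patch(), np.random.default_rng(seed), cfg)
        assert set(np.unique(q.gt)) <= {0, 1}
        assert set(np.unique(q.wml)) <= {0, 1}
        assert q.is_positive == bool(q.gt.any())


def test_spatial_transforms_align_channels_and_masks():
    """A coordinate-indicator volume must land on the same voxels in the
    channels as the gt mask does (affine disabled: exact voxel permutation)."""
    cfg = SamplingConfig(enable_affine=False, intensity_shift=0.0)
    edge = 8
    marker = np.zeros((edge,) * 3)
    marker[1, 2, 3] = 1.0
    p = Patch(
        channels=np.stack([marker] * 3),
        gt=marker.astype(np.uint8),
        wml=marker.astype(np.uint8),
        origin=(0, 0, 0),
        center_kind="cel_centered",
        is_positive=True,
    )
    for seed in range(30):
        q = augment(p, np.random.default_rng(seed), cfg)
        np.testing.assert_array_equal(q.channels[0] > 0.5, q.gt.astype(bool))
        np.testing.assert_array_equal(q.gt, q.wml)


def test_intensity_shift_touches_channels_only_and_is_bounded():
    cfg = SamplingConfig(enable_flip=False, enable_rot90=False, enable_affine=False)
    p = _toy_patch()
    shifts = []
    for seed in range(50):
        q = augment(p, np.random.default_rng(seed), cfg)
        delta = q.channels - p.channels
        assert np.ptp(delta) == pytest.approx(0.0, abs=1e-12)  # one scalar shift
        shifts.append(delta.flat[0])
        np.testing.assert_array_equal(q.gt, p.gt)
    assert max(np.abs(shifts)) <= cfg.intensity_shift
    assert np.std(shifts) > 0.05  # actually random, not constant


def test_sampling_config_validation():
    with pytest.raises(ValueError):
        SamplingConfig(initial_patch_mm=32, final_patch_mm=48)
    with pytest.raises(ValueError):
        SamplingConfig(positive_fraction=1.5)
    with pytest.raises(ValueError):
        SamplingConfig(patches_per_scan=0)
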