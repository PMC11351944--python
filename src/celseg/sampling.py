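"""Intensity normalization and the two-stage patch sampling strategy.

Training patches are drawn where lesions can actually occur: for a
CEL-positive scan one third of the patches are centered on CEL voxels and
the rest on WML voxels; CEL-free scans contribute WML-centered patches
only. A first crop of 64^3 is followed by a random 48^3 sub-crop, then
augmentation (axis flips, 90-degree rotations, a small random affine, and a
uniform intensity shift of up to +/-0.25 applied to the image channels
only).

A patch is *positive* when its ground-truth crop contains at least one CEL
voxel — the label is defined by content, not by which mask the center was
drawn from, since a WML-centered patch can incidentally contain a CEL.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .phantom import ScanBundle

__all__ = [
    "SamplingConfig",
    "Patch",
    "zscore_normalize",
    "normalize_bundle",
    "sample_patch_centers",
    "extract_patch",
    "random_subcrop",
    "augment",
]


@dataclass
class SamplingConfig:
    patches_per_scan: int = 32
    initial_patch_mm: int = 64     # edge of the first crop (1 mm voxels)
    final_patch_mm: int = 48       # edge after the random sub-crop
    positive_fraction: float = 1.0 / 3.0
    intensity_shift: float = 0.25
    enable_flip: bool = True
    enable_rot90: bool = True
    enable_affine: bool = True
    affine_max_rotation_deg: float = 10.0
    affine_scale_range: tuple[float, float] = (0.9, 1.1)
    inference_overlap: float = 0.5  # window overlap for WML-tiled inference

    def __post_init__(self):
        if self.final_patch_mm > self.initial_patch_mm:
            raise ValueError("final_patch_mm must be <= initial_patch_mm")
        if not 0.0 <= self.positive_fraction <= 1.0:
            raise ValueError("positive_fraction must be in [0, 1]")
        if self.patches_per_scan < 1:
            raise ValueError("patches_per_scan must be >= 1")


@dataclass
class Patch:
    """A multi-channel crop with its ground truth and provenance."""

    channels: np.ndarray          # (3, E, E, E)
    gt: np.ndarray                # (E, E, E) binary
    wml: np.ndarray               # (E, E, E) binary
    origin: tuple[int, int, int]  # voxel offset of the crop in the source grid
    center_kind: str              # "cel_centered" | "wml_centered"
    is_positive: bool             # gt contains >= 1 CEL voxel

    def __post_init__(self):
        if self.channels.shape[1:] != self.gt.shape or self.gt.shape != self.wml.shape:
            raise ValueError("channels, gt and wml must share spatial shape")
        if bool(self.gt.any()) != self.is_positive:
            raise ValueError("is_positive inconsistent with gt content")

    @property
    def edge(self) -> int:
        return self.gt.shape[0]


def zscore_normalize(volume: np.ndarray, brain_mask: np.ndarray) -> np.ndarray:
    """Standardize intensities to zero mean, unit s.d. over the brain mask.

    Background (mask-zero) voxels are set to 0. Statistics are per volume —
    never pooled across scans or channels.
    """
    mask = np.asarray(brain_mask, dtype=bool)
    if mask.sum() < 2:
        raise ValueError("brain mask must contain at least 2 voxels")
    vals = volume[mask]
    sd = vals.std()
    if sd == 0:
        raise ValueError("constant image within mask: zero variance")
    out = np.zeros_like(volume, dtype=np.float64)
    out[mask] = (vals - vals.mean()) / sd
    return out


def normalize_bundle(bundle: ScanBundle) -> ScanBundle:
    """Z-score each channel over the brain (nonzero-intensity) voxels."""
    brain = bundle.t1_pre != 0
    return ScanBundle(
        t1_pre=zscore_normalize(bundle.t1_pre, brain),
        t1_post=zscore_normalize(bundle.t1_post, brain),
        flair=zscore_normalize(bundle.flair, brain),
        wml_mask=bundle.wml_mask,
        cel_mask=bundle.cel_mask,
        patient_id=bundle.patient_id,
        scan_id=bundle.scan_id,
        voxel_size_mm=bundle.voxel_size_mm,
    )


def sample_patch_centers(
    bundle: ScanBundle, config: SamplingConfig, rng: np.random.Generator
):
    """Draw patch centers: round(positive_fraction * patches_per_scan) on CEL
    voxels for a positive scan, the rest on WML voxels; all on WML voxels for
    a CEL-free scan. Centers are drawn uniformly over mask voxels, so larger
    lesions are sampled proportionally more often."""
    wml_voxels = np.argwhere(bundle.wml_mask)
    if len(wml_voxels) == 0:
        raise ValueError("no sampling support: WML mask is empty")
    n = config.patches_per_scan
    n_cel = round(config.positive_fraction * n) if bundle.has_cels else 0
    centers = []
    if n_cel:
        cel_voxels = np.argwhere(bundle.cel_mask)
        idx = rng.integers(len(cel_voxels), size=n_cel)
        centers += [(tuple(cel_voxels[i]), "cel_centered") for i in idx]
    idx = rng.integers(len(wml_voxels), size=n - n_cel)
    centers += [(tuple(wml_voxels[i]), "wml_centered") for i in idx]
    return centers


def extract_patch(
    bundle: ScanBundle, center, config: SamplingConfig, center_kind: str = "wml_centered"
) -> Patch:
    """Crop the initial-size block whose geometric center is `center`,
    clamping the window to the grid at boundaries."""
    edge = config.initial_patch_mm
    shape = bundle.shape
    origin = tuple(
        int(np.clip(c - edge // 2, 0, s - edge)) for c, s in zip(center, shape)
    )
    sl = tuple(slice(o, o + edge) for o in origin)
    gt = np.asarray(bundle.cel_mask[sl], dtype=np.uint8)
    return Patch(
        channels=bundle.channels()[(slice(None),) + sl].astype(np.float64),
        gt=gt,
        wml=np.asarray(bundle.wml_mask[sl], dtype=np.uint8),
        origin=origin,
        center_kind=center_kind,
        is_positive=bool(gt.any()),
    )


def random_subcrop(patch: Patch, config: SamplingConfig, rng: np.random.Generator) -> Patch:
    """Second crop: a final-size sub-block at a uniformly random offset."""
    e0, e1 = patch.edge, config.final_patch_mm
    if e0 != config.initial_patch_mm:
        raise ValueError("random_subcrop expects an initial-size patch")
    off = tuple(int(o) for o in rng.integers(0, e0 - e1 + 1, size=3))
    sl = tuple(slice(o, o + e1) for o in off)
    gt = patch.gt[sl]
    return Patch(
        channels=patch.channels[(slice(None),) + sl],
        gt=gt,
        wml=patch.wml[sl],
        origin=tuple(po + o for po, o in zip(patch.origin, off)),
        center_kind=patch.center_kind,
        is_positive=bool(gt.any()),
    )


def _random_affine_matrix(rng, config):
    ang = np.deg2rad(
        rng.uniform(-config.affine_max_rotation_deg, config.affine_max_rotation_deg, 3)
    )
    scale = rng.uniform(*config.affine_scale_range)
    rots = []
    for axis, a in enumerate(ang):
        c, s = np.cos(a), np.sin(a)
        r = np.eye(3)
        i, j = [k for k in range(3) if k != axis]
        r[i, i], r[i, j], r[j, i], r[j, j] = c, -s, s, c
        rots.append(r)
    return (rots[0] @ rots[1] @ rots[2]) * scale


def augment(
    patch: Patch, rng: np.random.Generator, config: SamplingConfig | None = None
) -> Patch:
    """Random flips, axis-pair 90-degree rotations, a small random affine,
    and an intensity shift. Spatial transforms are applied voxel-identically
    to channels, gt and wml (nearest-neighbour for the masks, so they stay
    binary); the intensity shift touches the image channels only."""
    config = config or SamplingConfig()
    ch, gt, wml = patch.channels, patch.gt, patch.wml

    if config.enable_flip:
        for axis in range(3):
            if rng.random() < 0.5:
                ch = np.flip(ch, axis=axis + 1)
                gt = np.flip(gt, axis=axis)
                wml = np.flip(wml, axis=axis)
    if config.enable_rot90:
        pairs = ((0, 1), (0, 2), (1, 2))
        a, b = pairs[rng.integers(3)]
        k = int(rng.integers(4))
        ch = np.rot90(ch, k=k, axes=(a + 1, b + 1))
        gt = np.rot90(gt, k=k, axes=(a, b))
        wml = np.rot90(wml, k=k, axes=(a, b))
    if config.enable_affine:
        mat = _random_affine_matrix(rng, config)
        c = (np.array(gt.shape) - 1) / 2.0
        offset = c - mat @ c
        ch = np.stack(
            [
                ndimage.affine_transform(v, mat, offset=offset, order=1)
                for v in ch
            ]
        )
        gt = ndimage.affine_transform(gt, mat, offset=offset, order=0)
        wml = ndimage.affine_transform(wml, mat, offset=offset, order=0)
    if config.intensity_shift > 0:
        ch = ch + rng.uniform(-config.intensity_shift, config.intensity_shift)

    gt = np.ascontiguousarray(gt, dtype=np.uint8)
    return Patch(
        channels=np.ascontiguousarray(ch, dtype=np.float64),
        gt=gt,
        wml=np.ascontiguousarray(wml, dtype=np.uint8),
        origin=patch.origin,
        center_kind=patch.center_kind,
        is_positive=bool(gt.any()),
    )
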