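"""Synthetic multi-contrast brain phantom with WML and CEL pathology.

Emulates the input bundle the segmentation pipeline expects from a real MS
scan session: co-registered, skull-stripped, 1 mm isotropic T1-weighted
pre/post-gadolinium and FLAIR volumes, a white-matter-lesion (WML) mask,
and a contrast-enhancing-lesion (CEL) ground-truth mask.

The statistical structure mirrors a clinical MS cohort: roughly 56% of
scans carry at least one CEL, positive scans average 3 CELs, lesion volumes
follow a right-skewed lognormal with mean ~136 mm^3 truncated at 3 voxels
(3 mm^3), CELs lie strictly inside WML components, WMLs are hyperintense on
FLAIR, CELs are hyperintense on post-contrast T1, and vessel-like tube
confounders are post-contrast-bright but lie entirely outside the WML mask
so only WML-overlap filtering can reject them. Intensities are
piecewise-constant tissue means plus Gaussian noise; no anatomy, bias field
or scanner effects are simulated.
"""

from __future__ import annotations

import gzip
import heapq
from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PhantomConfig",
    "ScanBundle",
    "generate_scan",
    "generate_cohort",
    "cohort_summary",
    "summarize_manifest",
    "write_bundle",
    "write_cohort",
    "read_bundle",
]

CHANNELS = ("t1_pre", "t1_post", "flair")

DEFAULT_CONTRAST = {
    # tissue mean intensity (arbitrary units) per channel
    "t1_pre": {"brain": 1.0, "wml": 0.90, "cel": 0.95, "confounder": 1.0},
    "t1_post": {"brain": 1.0, "wml": 0.95, "cel": 2.00, "confounder": 2.0},
    "flair": {"brain": 1.0, "wml": 1.80, "cel": 1.80, "confounder": 1.0},
}


@dataclass
class PhantomConfig:
    """Parameters of the synthetic cohort; defaults mirror the reference
    cohort's composition (positive-scan fraction 208/372, mean 3 CELs per
    positive scan, mean CEL volume ~136 mm^3, minimum lesion 3 voxels)."""

    grid_shape: tuple[int, int, int] = (96, 96, 96)
    voxel_size_mm: float = 1.0
    n_wml: int = 8
    wml_volume_range_mm3: tuple[float, float] = (100.0, 4000.0)
    p_scan_has_cels: float = 208.0 / 372.0
    cel_count_mean: float = 3.0
    # lognormal(mu, sigma) of volume in mm^3; exp(mu + sigma^2/2) ~= 136
    cel_volume_lognormal_params: tuple[float, float] = (4.07, 1.30)
    min_cel_volume_mm3: float = 3.0
    contrast_levels: dict = field(default_factory=lambda: DEFAULT_CONTRAST)
    noise_sigma: float = 0.15
    n_confounders: int = 3
    ring_fraction: float = 0.0   # fraction of CELs rendered as hollow shells
    bias_field: bool = False
    seed: int | None = None

    def __post_init__(self):
        self.grid_shape = tuple(int(s) for s in self.grid_shape)
        if any(s < 1 for s in self.grid_shape):
            raise ValueError("grid_shape axes must be positive")
        if self.min_cel_volume_mm3 < 3:
            raise ValueError("min_cel_volume_mm3 must be >= 3 (3-voxel minimum)")
        if not 0.0 <= self.p_scan_has_cels <= 1.0:
            raise ValueError("p_scan_has_cels must be in [0, 1]")
        if self.n_wml < 1:
            raise ValueError("n_wml must be >= 1")
        if self.wml_volume_range_mm3[0] <= 0:
            raise ValueError("WML volumes must be positive")
        if self.cel_count_mean < 1:
            raise ValueError("cel_count_mean must be >= 1 (count of a positive scan)")
        if self.noise_sigma < 0 or self.n_confounders < 0:
            raise ValueError("noise_sigma and n_confounders must be >= 0")


@dataclass
class ScanBundle:
    """One scan's volumes on a shared grid, plus identifiers."""

    t1_pre: np.ndarray
    t1_post: np.ndarray
    flair: np.ndarray
    wml_mask: np.ndarray
    cel_mask: np.ndarray
    patient_id: str
    scan_id: str
    voxel_size_mm: float = 1.0

    def __post_init__(self):
        shapes = {v.shape for v in self.volumes()}
        if len(shapes) != 1:
            raise ValueError(f"all volumes must share one grid, got {shapes}")
        for m in (self.wml_mask, self.cel_mask):
            vals = np.unique(m)
            if not np.isin(vals, (0, 1)).all():
                raise ValueError("masks must be binary")
        cel = np.asarray(self.cel_mask, dtype=bool)
        wml = np.asarray(self.wml_mask, dtype=bool)
        if np.any(cel & ~wml):
            raise ValueError("cel_mask must be a subset of wml_mask")

    def volumes(self):
        return (self.t1_pre, self.t1_post, self.flair, self.wml_mask, self.cel_mask)

    @property
    def shape(self):
        return self.t1_pre.shape

    @property
    def has_cels(self) -> bool:
        return bool(self.cel_mask.any())

    def channels(self) -> np.ndarray:
        """Stacked (3, D, H, W) intensity channels in t1_pre/t1_post/flair order."""
        return np.stack([self.t1_pre, self.t1_post, self.flair])


_STRUCT26 = ndimage.generate_binary_structure(3, 3)


def _ellipsoid_mask(shape, center, semi_axes):
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    r = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi_axes))
    return r <= 1.0


def _place_blob(rng, support_dist, target_volume_mm3, voxel_vol):
    """Choose a center inside `support_dist > margin` for a blob of the
    requested volume; returns (center, radius_voxels) or None."""
    radius = (3.0 * target_volume_mm3 / (4.0 * np.pi)) ** (1.0 / 3.0) / voxel_vol ** (1 / 3)
    cand = np.argwhere(support_dist > radius + 1.0)
    if len(cand) == 0:
        cand = np.argwhere(support_dist > 1.0)
        if len(cand) == 0:
            return None
    return tuple(cand[rng.integers(len(cand))]), radius


def _carve_k_nearest(component_voxels: np.ndarray, center, k: int) -> np.ndarray:
    """A connected blob of exactly k voxels inside the component, grown
    from `center` by repeatedly adding the 26-adjacent component voxel
    closest to the center (deterministic tie-break).

    Plain k-nearest selection can leave stragglers when the component is
    concave; region growing keeps the lesion a single connected component.
    """
    k = min(k, len(component_voxels))
    d2 = ((component_voxels - np.asarray(center)) ** 2).sum(axis=1)
    index = {tuple(v): i for i, v in enumerate(component_voxels)}
    start = int(np.argmin(d2))
    chosen: list[int] = []
    seen = {start}
    heap = [(d2[start], tuple(component_voxels[start]))]
    offsets = [
        (a, b, c)
        for a in (-1, 0, 1)
        for b in (-1, 0, 1)
        for c in (-1, 0, 1)
        if (a, b, c) != (0, 0, 0)
    ]
    while heap and len(chosen) < k:
        _, vox = heapq.heappop(heap)
        chosen.append(index[vox])
        for off in offsets:
            nb = (vox[0] + off[0], vox[1] + off[1], vox[2] + off[2])
            j = index.get(nb)
            if j is not None and j not in seen:
                seen.add(j)
                heapq.heappush(heap, (d2[j], nb))
    return component_voxels[chosen]


def generate_scan(
    config: PhantomConfig,
    rng: np.random.Generator,
    patient_id: str = "P0001",
    scan_id: str = "S0001",
    force_cel_volumes_mm3=None,
) -> ScanBundle:
    """Generate one synthetic scan bundle.

    ``force_cel_volumes_mm3`` overrides the stochastic CEL count/volumes
    with an explicit list (used to construct edge cases such as a single
    minimum-size 3-voxel lesion).
    """
    shape = config.grid_shape
    if any(s < 64 for s in shape) and force_cel_volumes_mm3 is None:
        raise ValueError(
            f"grid {shape} too small: each axis must be >= 64 to hold an "
            "initial sampling patch"
        )
    voxel_vol = config.voxel_size_mm**3

    # brain: centered ellipsoid covering most of the grid
    center = tuple((s - 1) / 2.0 for s in shape)
    brain = _ellipsoid_mask(shape, center, tuple(0.45 * s for s in shape))
    brain_dist = ndimage.distance_transform_edt(brain)

    # WML components
    wml = np.zeros(shape, dtype=bool)
    lo, hi = config.wml_volume_range_mm3
    for _ in range(config.n_wml):
        vol = rng.uniform(lo, hi)
        placed = _place_blob(rng, brain_dist, vol, voxel_vol)
        if placed is None:
            continue
        c, r = placed
        ratios = rng.uniform(0.6, 1.6, size=3)
        ratios /= ratios.prod() ** (1 / 3)
        wml |= _ellipsoid_mask(shape, c, tuple(r * ratios))
    wml &= brain
    if not wml.any():  # pathological config; keep the bundle valid
        raise ValueError("no WML component could be placed on this grid")

    # CELs strictly inside WML components
    cel = np.zeros(shape, dtype=bool)
    if force_cel_volumes_mm3 is not None:
        volumes = list(force_cel_volumes_mm3)
    elif rng.random() < config.p_scan_has_cels:
        # 1 + Poisson(mean - 1): positive count with the configured mean
        n_cels = 1 + rng.poisson(config.cel_count_mean - 1.0)
        mu, sigma = config.cel_volume_lognormal_params
        volumes = np.maximum(
            rng.lognormal(mu, sigma, size=n_cels), config.min_cel_volume_mm3
        ).tolist()
    else:
        volumes = []

    if volumes:
        labels, n_comp = ndimage.label(wml, structure=_STRUCT26)
        comp_voxels = [np.argwhere(labels == i + 1) for i in range(n_comp)]
        sizes = np.array([len(v) for v in comp_voxels], dtype=float)
        for vol in volumes:
            k = max(int(round(vol / voxel_vol)), int(round(config.min_cel_volume_mm3)))
            comp = comp_voxels[rng.choice(n_comp, p=sizes / sizes.sum())]
            seed_voxel = comp[rng.integers(len(comp))]
            chosen = _carve_k_nearest(comp, seed_voxel, k)
            if config.ring_fraction > 0 and rng.random() < config.ring_fraction and len(chosen) > 9:
                core = max(3, int(0.3 * len(chosen)))
                chosen = chosen[core:]  # drop the innermost voxels -> shell
            cel[tuple(chosen.T)] = True
    # generator guarantee: strict subset
    cel &= wml

    # vessel-like confounder tubes, post-contrast bright, outside WML
    conf = np.zeros(shape, dtype=bool)
    for _ in range(config.n_confounders):
        cand = np.argwhere(brain_dist > 4.0)
        start = cand[rng.integers(len(cand))].astype(float)
        direction = rng.normal(size=3)
        direction /= np.linalg.norm(direction)
        length = rng.uniform(15, 35)
        t = np.arange(0.0, length, 0.5)
        pts = np.round(start + t[:, None] * direction).astype(int)
        pts = pts[((pts >= 0) & (pts < np.array(shape))).all(axis=1)]
        tube = np.zeros(shape, dtype=bool)
        tube[tuple(pts.T)] = True
        conf |= ndimage.binary_dilation(tube, structure=_STRUCT26)
    conf &= brain & ~wml  # confounders never intersect the WML mask

    # intensities: piecewise-constant tissue means + noise inside the brain
    levels = config.contrast_levels
    out = {}
    for ch in CHANNELS:
        v = np.zeros(shape, dtype=np.float64)
        v[brain] = levels[ch]["brain"]
        v[wml] = levels[ch]["wml"]
        v[conf] = levels[ch]["confounder"]
        v[cel] = levels[ch]["cel"]
        if config.bias_field:
            g = np.ogrid[tuple(slice(0, s) for s in shape)]
            ramp = sum((gi - c) / s for gi, c, s in zip(g, center, shape))
            v[brain] *= 1.0 + 0.1 * ramp[brain]
        if config.noise_sigma > 0:
            v[brain] += rng.normal(0.0, config.noise_sigma, size=int(brain.sum()))
        out[ch] = v

    return ScanBundle(
        t1_pre=out["t1_pre"],
        t1_post=out["t1_post"],
        flair=out["flair"],
        wml_mask=wml.astype(np.uint8),
        cel_mask=cel.astype(np.uint8),
        patient_id=patient_id,
        scan_id=scan_id,
        voxel_size_mm=config.voxel_size_mm,
    )


def generate_cohort(
    config: PhantomConfig,
    n_scans: int,
    n_patients: int,
    rng: np.random.Generator,
) -> list[ScanBundle]:
    """Generate a cohort; some patients own several scans, as in a
    longitudinal MS cohort where a subset of patients has repeat visits."""
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    if n_patients > n_scans:
        raise ValueError("n_patients must be <= n_scans")
    owners = list(range(n_patients))  # everyone gets one scan
    owners += list(rng.integers(0, n_patients, size=n_scans - n_patients))
    bundles = []
    for i, p in enumerate(owners):
        bundles.append(
            generate_scan(
                config, rng, patient_id=f"P{p + 1:04d}", scan_id=f"S{i + 1:04d}"
            )
        )
    return bundles


def _count_cels(mask: np.ndarray) -> int:
    return int(ndimage.label(mask, structure=_STRUCT26)[1])


def cohort_manifest(bundles) -> pd.DataFrame:
    """Per-scan table: patient, scan, CEL count and total CEL volume."""
    rows = []
    for b in bundles:
        n = _count_cels(b.cel_mask)
        rows.append(
            {
                "patient_id": b.patient_id,
                "scan_id": b.scan_id,
                "has_cels": n > 0,
                "n_cels": n,
                "cel_volume_mm3": float(b.cel_mask.sum()) * b.voxel_size_mm**3,
            }
        )
    return pd.DataFrame(rows)


def summarize_manifest(manifest: pd.DataFrame) -> dict:
    """Cohort composition summary from a per-scan manifest."""
    if len(manifest) == 0:
        raise ValueError("empty cohort")
    pos = manifest[manifest["n_cels"] > 0]
    total_cels = int(manifest["n_cels"].sum())
    total_vol = float(manifest["cel_volume_mm3"].sum())
    return {
        "n_patients": int(manifest["patient_id"].nunique()),
        "n_scans": int(len(manifest)),
        "n_scans_with_cels": int(len(pos)),
        "n_scans_without_cels": int(len(manifest) - len(pos)),
        "total_cels": total_cels,
        "mean_cels_per_positive_scan": (
            total_cels / len(pos) if len(pos) else float("nan")
        ),
        "mean_cels_per_scan": total_cels / len(manifest),
        "mean_cel_volume_mm3": (
            total_vol / total_cels if total_cels else float("nan")
        ),
    }


def cohort_summary(bundles) -> dict:
    """Summarize a list of ScanBundles (counts via 26-connected components)."""
    if not bundles:
        raise ValueError("empty cohort")
    return summarize_manifest(cohort_manifest(bundles))


# ---- NIfTI round-trip ----------------------------------------------------

_SUFFIXES = {
    "t1_pre": "_t1.nii.gz",
    "t1_post": "_t1c.nii.gz",
    "flair": "_flair.nii.gz",
    "wml_mask": "_wml.nii.gz",
    "cel_mask": "_gt.nii.gz",
}


def _affine(voxel_size_mm: float) -> np.ndarray:
    return np.diag([voxel_size_mm] * 3 + [1.0])  # RAS, isotropic


def _save_nifti_deterministic(img: nib.Nifti1Image, path: Path) -> None:
    # gzip with mtime=0 so identical data yields byte-identical files
    raw = img.to_bytes()
    with open(path, "wb") as fh:
        with gzip.GzipFile(fileobj=fh, mode="wb", mtime=0) as gz:
            gz.write(raw)


def write_bundle(bundle: ScanBundle, outdir) -> list[Path]:
    """Write the five volumes as `<scan_id>_{t1,t1c,flair,wml,gt}.nii.gz`."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    aff = _affine(bundle.voxel_size_mm)
    paths = []
    for attr, suffix in _SUFFIXES.items():
        data = getattr(bundle, attr)
        dtype = np.uint8 if attr.endswith("_mask") else np.float32
        img = nib.Nifti1Image(np.asarray(data, dtype=dtype), aff)
        path = outdir / f"{bundle.scan_id}{suffix}"
        _save_nifti_deterministic(img, path)
        paths.append(path)
    return paths


def write_cohort(bundles, outdir) -> Path:
    """Write all bundles plus a manifest.csv; returns the manifest path."""
    outdir = Path(outdir)
    for b in bundles:
        write_bundle(b, outdir)
    manifest = cohort_manifest(bundles)
    path = outdir / "manifest.csv"
    manifest.to_csv(path, index=False)
    return path


def read_bundle(
    t1, t1c, flair, wml, gt=None, patient_id="P0000", scan_id="S0000"
) -> ScanBundle:
    """Load a bundle from NIfTI paths (ground truth optional)."""
    vols = [np.asarray(nib.load(str(p)).dataobj, dtype=np.float64)
            for p in (t1, t1c, flair, wml)]
    zooms = nib.load(str(t1)).header.get_zooms()[:3]
    cel = (
        np.asarray(nib.load(str(gt)).dataobj, dtype=np.uint8)
        if gt is not None
        else np.zeros_like(vols[3], dtype=np.uint8)
    )
    return ScanBundle(
        t1_pre=vols[0],
        t1_post=vols[1],
        flair=vols[2],
        wml_mask=vols[3].astype(np.uint8),
        cel_mask=cel,
        patient_id=patient_id,
        scan_id=scan_id,
        voxel_size_mm=float(zooms[0]),
    )
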