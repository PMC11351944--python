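"""Connected-component analysis and rule-based lesion filtering.

Predicted CEL masks are cleaned with two rules applied as a conjunction:

* minimum size — components smaller than 3 voxels are deleted (the smallest
  real CEL considered is 3 voxels = 3 mm^3 at 1 mm isotropic);
* WML overlap — a predicted component with less than 10% of its own voxels
  inside the WML mask is deleted (a CEL is by definition the acute part of
  a white matter lesion; post-contrast-bright structures outside WMLs, such
  as veins, are false positives). The boundary is kept at exactly 10%.

The overlap fraction is computed over the predicted lesion's voxels, not
over the WML mask: the alternative reading would reject nearly every small
lesion inside a large WML.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

__all__ = ["LesionComponent", "LesionSet", "label_components", "filter_lesions"]

_STRUCTS = {
    6: ndimage.generate_binary_structure(3, 1),
    18: ndimage.generate_binary_structure(3, 2),
    26: ndimage.generate_binary_structure(3, 3),
}


@dataclass
class LesionComponent:
    label_id: int
    voxels: np.ndarray            # (n, 3) 0-based indices
    volume_mm3: float
    wml_overlap_fraction: float | None = None

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


@dataclass
class LesionSet:
    components: list
    grid_shape: tuple
    voxel_size_mm: float = 1.0

    def __len__(self):
        return len(self.components)

    def to_mask(self) -> np.ndarray:
        mask = np.zeros(self.grid_shape, dtype=np.uint8)
        for c in self.components:
            mask[tuple(c.voxels.T)] = 1
        return mask


def label_components(
    mask: np.ndarray, connectivity: int = 26, voxel_size_mm: float = 1.0
) -> LesionSet:
    """Maximal connected components of a binary mask (default 26-neighbour,
    the common choice in MS lesion tooling)."""
    if connectivity not in _STRUCTS:
        raise ValueError("connectivity must be one of 6, 18, 26")
    mask = np.asarray(mask)
    if not np.isin(np.unique(mask), (0, 1)).all():
        raise ValueError("mask must be binary")
    labels, n = ndimage.label(mask, structure=_STRUCTS[connectivity])
    voxel_vol = voxel_size_mm**3
    comps = []
    if n:
        all_voxels = np.argwhere(labels > 0)
        ids = labels[tuple(all_voxels.T)]
        order = np.argsort(ids, kind="stable")
        all_voxels, ids = all_voxels[order], ids[order]
        bounds = np.searchsorted(ids, np.arange(1, n + 2))
        for i in range(n):
            vox = all_voxels[bounds[i] : bounds[i + 1]]
            comps.append(
                LesionComponent(
                    label_id=i + 1, voxels=vox, volume_mm3=len(vox) * voxel_vol
                )
            )
    return LesionSet(components=comps, grid_shape=mask.shape, voxel_size_mm=voxel_size_mm)


def filter_lesions(
    pred: LesionSet,
    wml_mask: np.ndarray,
    min_voxels: int = 3,
    min_wml_fraction: float = 0.10,
) -> LesionSet:
    """Keep components with >= min_voxels voxels AND WML-overlap fraction
    >= min_wml_fraction (strictly below removes; the rules commute)."""
    wml = np.asarray(wml_mask, dtype=bool)
    if wml.shape != pred.grid_shape:
        raise ValueError("WML mask grid does not match the lesion set grid")
    kept = []
    for c in pred.components:
        frac = float(wml[tuple(c.voxels.T)].mean())
        c.wml_overlap_fraction = frac
        if c.n_voxels >= min_voxels and frac >= min_wml_fraction:
            kept.append(c)
    return LesionSet(
        components=kept, grid_shape=pred.grid_shape, voxel_size_mm=pred.voxel_size_mm
    )
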