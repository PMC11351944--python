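"""WML-guided patch inference and whole-image reconstruction.

Validation/test inference parallels the training sampling: instead of a
sliding window over the whole head, patches are taken only where white
matter lesions were detected — the only regions where a CEL can exist.
Windows deterministically tile the grid with 50% overlap and only windows
intersecting the WML mask are predicted, which guarantees every WML voxel
is covered by at least one patch. By default the per-window probabilities
of a voxel are averaged before thresholding ("mean" mode): overlapping
windows see the same voxel in different instance-normalization contexts,
and averaging cancels that context noise. The alternative "binary" mode
binarizes each window first and combines by sum-then-clip-to-1 (a
voxel-wise union, hence order-independent); it is far more permissive,
since any one of up to eight overlapping windows can switch a voxel on,
and it inflates small false-positive components accordingly.
"""

from __future__ import annotations

import warnings

import numpy as np

from .network import UNet3D, predict_patch
from .phantom import ScanBundle
from .sampling import SamplingConfig, normalize_bundle

__all__ = ["tile_wml_windows", "reconstruct", "infer_scan"]


def _axis_origins(size: int, edge: int, step: int):
    if edge >= size:
        return [0]
    origins = list(range(0, size - edge + 1, step))
    if origins[-1] != size - edge:
        origins.append(size - edge)
    return origins


def tile_wml_windows(wml_mask: np.ndarray, edge: int, overlap: float = 0.5):
    """Origins of edge^3 windows tiling the grid that intersect the WML mask.

    The pre-filter tiling covers the whole grid, so every WML voxel lies in
    at least one returned window.
    """
    if not 0.0 <= overlap < 1.0:
        raise ValueError("overlap must be in [0, 1)")
    step = max(1, int(round(edge * (1.0 - overlap))))
    shape = wml_mask.shape
    wml = np.asarray(wml_mask, dtype=bool)
    out = []
    for od in _axis_origins(shape[0], edge, step):
        for oh in _axis_origins(shape[1], edge, step):
            for ow in _axis_origins(shape[2], edge, step):
                if wml[od : od + edge, oh : oh + edge, ow : ow + edge].any():
                    out.append((od, oh, ow))
    return out


def reconstruct(patches, origins, grid_shape) -> np.ndarray:
    """Map binary patch predictions back to the grid; overlapping voxel
    predictions are summed and values exceeding 1 clipped to 1."""
    acc = np.zeros(grid_shape, dtype=np.int32)
    for patch, origin in zip(patches, origins):
        patch = np.asarray(patch)
        sl = []
        for o, e, s in zip(origin, patch.shape, grid_shape):
            if o < 0 or o + e > s:
                raise ValueError(f"patch at origin {origin} exceeds grid {grid_shape}")
            sl.append(slice(o, o + e))
        acc[tuple(sl)] += patch.astype(np.int32)
    return np.minimum(acc, 1).astype(np.uint8)


def infer_scan(
    model: UNet3D,
    bundle: ScanBundle,
    config: SamplingConfig | None = None,
    threshold: float = 0.5,
    batch_size: int = 8,
    mode: str = "mean",
    normalized: bool = False,
) -> np.ndarray:
    """Predict a whole-scan binary CEL mask by tiled WML-window inference.

    ``mode='mean'`` (default) averages window probabilities per voxel,
    then thresholds. ``mode='binary'`` binarizes each window at
    ``threshold`` before the sum-and-clip combination (a union). Set
    ``normalized=True`` if the bundle channels are already z-scored.
    """
    config = config or SamplingConfig()
    if not bundle.wml_mask.any():
        warnings.warn(
            "empty WML mask: no CEL can exist outside WMLs; returning zeros",
            stacklevel=2,
        )
        return np.zeros(bundle.shape, dtype=np.uint8)
    norm = bundle if normalized else normalize_bundle(bundle)
    channels = norm.channels()
    edge = config.final_patch_mm
    origins = tile_wml_windows(bundle.wml_mask, edge, config.inference_overlap)

    prob_sum = np.zeros(bundle.shape) if mode == "mean" else None
    count = np.zeros(bundle.shape, dtype=np.int32) if mode == "mean" else None
    binary_patches = []
    for start in range(0, len(origins), batch_size):
        chunk = origins[start : start + batch_size]
        batch = np.stack(
            [
                channels[:, o[0] : o[0] + edge, o[1] : o[1] + edge, o[2] : o[2] + edge]
                for o in chunk
            ]
        )
        probs = predict_patch(model, batch)[:, 0]
        for o, p in zip(chunk, probs):
            if mode == "mean":
                sl = tuple(slice(oo, oo + edge) for oo in o)
                prob_sum[sl] += p
                count[sl] += 1
            else:
                binary_patches.append((p >= threshold).astype(np.uint8))
    if mode == "mean":
        with np.errstate(invalid="ignore"):
            mean = np.where(count > 0, prob_sum / np.maximum(count, 1), 0.0)
        return (mean >= threshold).astype(np.uint8)
    return reconstruct(binary_patches, origins, bundle.shape)
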