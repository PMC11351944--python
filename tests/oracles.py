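"""Independent brute-force oracles used by the unit and acceptance suites.

These deliberately avoid the library code paths they check: pure-python
loops and set arithmetic only.
"""

import numpy as np


def dice_loss_loop(pred, gt, epsilon=1e-5):
    """Per-voxel python-loop soft dice loss."""
    inter = s_p = s_g = 0.0
    for p, g in zip(np.ravel(pred), np.ravel(gt)):
        inter += p * g
        s_p += p
        s_g += g
    return 1.0 - (2.0 * inter + epsilon) / (s_p + s_g + epsilon)


def focal_loss_loop(pred, gt, gamma=2.0, clamp=1e-7):
    """Per-voxel python-loop focal loss."""
    total = 0.0
    vals = list(zip(np.ravel(pred), np.ravel(gt)))
    for p, g in vals:
        p = min(max(p, clamp), 1.0 - clamp)
        pt = p if g >= 0.5 else 1.0 - p
        total += -((1.0 - pt) ** gamma) * np.log(pt)
    return total / len(vals)


def flood_fill_labels(mask, conn=26):
    """BFS connected-component labeling."""
    offs = []
    for a in (-1, 0, 1):
        for b in (-1, 0, 1):
            for c in (-1, 0, 1):
                if (a, b, c) == (0, 0, 0):
                    continue
                order = abs(a) + abs(b) + abs(c)
                if (conn == 6 and order == 1) or (conn == 18 and order <= 2) or conn == 26:
                    offs.append((a, b, c))
    labels = np.zeros(mask.shape, int)
    nxt = 0
    for start in np.argwhere(mask):
        start = tuple(start)
        if labels[start]:
            continue
        nxt += 1
        queue = [start]
        labels[start] = nxt
        while queue:
            v = queue.pop()
            for o in offs:
                w = (v[0] + o[0], v[1] + o[1], v[2] + o[2])
                if all(0 <= wi < si for wi, si in zip(w, mask.shape)):
                    if mask[w] and not labels[w]:
                        labels[w] = nxt
                        queue.append(w)
    return labels, nxt


def match_counts_pairwise(pred_sets, gt_sets):
    """Exhaustive pairwise overlap matching: (tp, fn, fp) lesion counts."""
    tp = sum(1 for g in gt_sets if any(g & p for p in pred_sets))
    fn = len(gt_sets) - tp
    fp = sum(1 for p in pred_sets if not any(p & g for g in gt_sets))
    return tp, fn, fp


def or_accumulate(patches, origins, grid_shape):
    """Voxel-wise OR reconstruction."""
    out = np.zeros(grid_shape, bool)
    for p, o in zip(patches, origins):
        sl = tuple(slice(oo, oo + e) for oo, e in zip(o, p.shape))
        out[sl] |= p.astype(bool)
    return out.astype(np.uint8)
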