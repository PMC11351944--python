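"""Training loop, patient-level cross-validation, and the end-to-end demo.

Cross-validation folds are formed at the patient level: all scans of one
patient land in the same fold, so repeat visits can never leak between
training, validation and test. One fold is held out as test; of the rest,
one is validation and the others train the model. Model selection tracks
the whole-image validation Dice (computed through the full inference,
reconstruction and filtering path) and keeps the best checkpoint.

The reference training configuration is Adam at learning rate 5e-5 with
the imbalance-weighted dice+focal loss. The demo profile scales everything
to a desk CPU: a tiny-width 3-level network, 16^3 final patches, a
96^3 phantom grid and a 20-scan synthetic cohort.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nn
from .inference import infer_scan
from .losses import LossConfig, compute_rate_imbalance, starting_loss, weighted_loss
from .metrics import (
    DetectionCounts,
    dice_coefficient,
    false_positive_rate,
    match_lesions,
    strata_table,
    stratify_by_volume,
    true_positive_rate,
    whole_image_dsc,
)
from .network import NetworkConfig, build_model
from .phantom import PhantomConfig, cohort_manifest, generate_cohort, summarize_manifest
from .postprocess import filter_lesions, label_components
from .sampling import (
    SamplingConfig,
    augment,
    extract_patch,
    normalize_bundle,
    random_subcrop,
    sample_patch_centers,
)

__all__ = [
    "TrainConfig",
    "split_folds",
    "train_fold",
    "run_end_to_end",
    "evaluate_bundles",
    "compare_losses_on_patches",
    "demo_profile",
    "load_profile",
]


@dataclass
class TrainConfig:
    optimizer: str = "adam"
    learning_rate: float = 5e-5
    n_folds: int = 11
    epochs: int = 100
    batch_size: int = 8
    seed: int = 0
    loss: str = "weighted"        # "starting" | "weighted"
    rate_mode: str = "auto"       # "auto": measure neg:pos ratio on epoch 1
    val_interval: int = 5
    early_stop_patience: int = 20

    def __post_init__(self):
        if self.n_folds < 3:
            raise ValueError("n_folds must be >= 3 (train/val/test)")
        if self.learning_rate <= 0:
            raise ValueError("learning_rate must be > 0")
        if self.loss not in ("starting", "weighted"):
            raise ValueError("loss must be 'starting' or 'weighted'")


def split_folds(patients, n_folds: int, rng: np.random.Generator):
    """Partition patient ids into n_folds near-equal folds.

    ``patients`` is a sequence of patient ids or a mapping patient -> scans;
    every scan of a patient follows its patient into a single fold.
    """
    ids = sorted(patients.keys() if isinstance(patients, dict) else set(patients))
    if len(ids) < n_folds:
        raise ValueError(f"need >= {n_folds} patients, got {len(ids)}")
    ids = np.array(ids, dtype=object)
    rng.shuffle(ids)
    return [list(fold) for fold in np.array_split(ids, n_folds)]


def _epoch_patches(bundles, sampling, rng):
    patches = []
    for b in bundles:
        for center, kind in sample_patch_centers(b, sampling, rng):
            p = extract_patch(b, center, sampling, center_kind=kind)
            p = random_subcrop(p, sampling, rng)
            patches.append(augment(p, rng, sampling))
    order = rng.permutation(len(patches))
    return [patches[i] for i in order]


def _validation_dsc(model, val_bundles, sampling):
    scores = []
    for b in val_bundles:
        pred = infer_scan(model, b, sampling)
        pred_set = filter_lesions(
            label_components(pred, voxel_size_mm=b.voxel_size_mm), b.wml_mask
        )
        gt_set = label_components(b.cel_mask, voxel_size_mm=b.voxel_size_mm)
        scores.append(whole_image_dsc(pred_set, gt_set))
    scores = np.asarray(scores, dtype=float)
    return float(np.nanmean(scores)) if np.isfinite(scores).any() else 0.0


def train_fold(
    train_bundles,
    val_bundles,
    network: NetworkConfig | None = None,
    sampling: SamplingConfig | None = None,
    loss_config: LossConfig | None = None,
    train_config: TrainConfig | None = None,
    rng: np.random.Generator | None = None,
):
    """Train one cross-validation rotation; returns (model, history).

    The model retains the parameters of the epoch with the highest
    whole-image validation Dice. The loss history carries one row per
    epoch; validation is run every ``val_interval`` epochs and at the end.
    """
    network = network or NetworkConfig()
    sampling = sampling or SamplingConfig()
    loss_config = loss_config or LossConfig()
    train_config = train_config or TrainConfig()
    rng = rng if rng is not None else np.random.default_rng(train_config.seed)
    if not train_bundles or not val_bundles:
        raise ValueError("train and validation sets must be non-empty")
    if not any(b.has_cels for b in val_bundles):
        raise ValueError(
            "validation set has no CEL-positive scan: the whole-image DSC "
            "selection metric is undefined; add a positive scan to the fold"
        )

    train_norm = [normalize_bundle(b) for b in train_bundles]
    model = build_model(network, rng)
    opt = nn.Adam(model.parameters(), lr=train_config.learning_rate)
    use_weighted = train_config.loss == "weighted"
    rate = loss_config.rate_imbalance
    rate_measured = train_config.rate_mode != "auto"

    best = {"dsc": -np.inf, "state": model.state_dict(), "epoch": 0}
    rows = []
    since_improve = 0
    for epoch in range(1, train_config.epochs + 1):
        patches = _epoch_patches(train_norm, sampling, rng)
        if not rate_measured:
            labels = [p.is_positive for p in patches]
            try:
                rate = compute_rate_imbalance(labels)
            except ValueError:
                rate = loss_config.rate_imbalance  # no positives this epoch
            loss_config = LossConfig(
                gamma=loss_config.gamma,
                dice_weight_starting=loss_config.dice_weight_starting,
                rate_imbalance=max(rate, 1e-6) if rate > 0 else loss_config.rate_imbalance,
                epsilon=loss_config.epsilon,
                eq5_literal=loss_config.eq5_literal,
            )
            rate_measured = True
        losses = []
        bs = train_config.batch_size
        for start in range(0, len(patches), bs):
            chunk = patches[start : start + bs]
            x = nn.Tensor(np.stack([p.channels for p in chunk]).astype(np.float32))
            gts = nn.Tensor(np.stack([p.gt[None] for p in chunk]).astype(np.float32))
            flags = np.array([p.is_positive for p in chunk])
            pred = model(x)
            if use_weighted:
                loss = weighted_loss(pred, gts, flags, loss_config)
            else:
                loss = starting_loss(pred, gts, loss_config)
            opt.zero_grad()
            loss.backward()
            opt.step()
            losses.append(float(loss.data))

        val_dsc = np.nan
        if epoch % train_config.val_interval == 0 or epoch == train_config.epochs:
            val_dsc = _validation_dsc(model, val_bundles, sampling)
            if val_dsc > best["dsc"]:
                best = {"dsc": val_dsc, "state": model.state_dict(), "epoch": epoch}
                since_improve = 0
            else:
                since_improve += train_config.val_interval
        rows.append(
            {
                "epoch": epoch,
                "train_loss": float(np.mean(losses)),
                "val_dsc": val_dsc,
                "best_dsc": best["dsc"] if np.isfinite(best["dsc"]) else np.nan,
                "rate_imbalance": rate,
            }
        )
        if since_improve >= train_config.early_stop_patience:
            break
    model.load_state_dict(best["state"])
    history = pd.DataFrame(rows)
    history.attrs["best_epoch"] = best["epoch"]
    history.attrs["best_dsc"] = best["dsc"]
    return model, history


def evaluate_bundles(model, bundles, sampling: SamplingConfig | None = None):
    """Infer, filter and score a list of scans at the lesion level.

    Returns (counts, match-like aggregate, report dict, strata table).
    """
    sampling = sampling or SamplingConfig()
    total = DetectionCounts()
    tp_pairs, fp_comps, fn_comps = [], [], []
    image_dscs = []
    for b in bundles:
        pred = infer_scan(model, b, sampling)
        pred_set = filter_lesions(
            label_components(pred, voxel_size_mm=b.voxel_size_mm), b.wml_mask
        )
        gt_set = filter_lesions(
            label_components(b.cel_mask, voxel_size_mm=b.voxel_size_mm),
            b.wml_mask,
            min_wml_fraction=0.0,
        )
        match = match_lesions(pred_set, gt_set)
        total = total + match.counts
        tp_pairs += match.tp_pairs
        fp_comps += match.fp_components
        fn_comps += match.fn_components
        if match.counts.n_tp > 0:
            image_dscs.append(dice_coefficient(pred_set.to_mask(), gt_set.to_mask()))
    from .metrics import LesionMatchResult  # aggregate across scans

    agg = LesionMatchResult(total, tp_pairs, fp_comps, fn_comps)
    report = {
        "n_tp": total.n_tp,
        "n_fp": total.n_fp,
        "n_fn": total.n_fn,
        "tpr": true_positive_rate(total),
        "fpr": false_positive_rate(total),
        "mean_lesion_dsc": (
            float(np.mean([d for _, _, d in tp_pairs])) if tp_pairs else float("nan")
        ),
        "mean_whole_image_dsc": (
            float(np.mean(image_dscs)) if image_dscs else float("nan")
        ),
    }
    return total, agg, report, strata_table(stratify_by_volume(agg))


# ---- profiles ------------------------------------------------------------


def demo_profile(seed: int = 0) -> dict:
    """Desk-scale profile: 20-scan synthetic cohort, tiny 3-level network,
    16^3 final patches, 50 epochs. Runs end to end on one CPU."""
    return {
        "phantom": PhantomConfig(grid_shape=(96, 96, 96)),
        "cohort": {"n_scans": 20, "n_patients": 17},
        "sampling": SamplingConfig(
            patches_per_scan=12, initial_patch_mm=24, final_patch_mm=16
        ),
        "network": NetworkConfig(
            encoder_filters=(4, 8, 16), decoder_filters=(16, 8, 4)
        ),
        "loss": LossConfig(),
        "train": TrainConfig(
            learning_rate=3e-3, n_folds=6, epochs=50, batch_size=8,
            seed=seed, val_interval=10, early_stop_patience=50,
        ),
        "seed": seed,
    }


_BLOCKS = {
    "phantom": PhantomConfig,
    "sampling": SamplingConfig,
    "network": NetworkConfig,
    "loss": LossConfig,
    "train": TrainConfig,
}


def load_profile(path) -> dict:
    """Load a YAML run profile; unspecified fields take their defaults."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    profile = {"seed": raw.get("seed", 0), "cohort": raw.get("cohort", {"n_scans": 20, "n_patients": 17})}
    for block, cls in _BLOCKS.items():
        kwargs = raw.get(block, {}) or {}
        for key in ("grid_shape", "encoder_filters", "decoder_filters",
                    "wml_volume_range_mm3", "cel_volume_lognormal_params",
                    "affine_scale_range"):
            if key in kwargs and isinstance(kwargs[key], list):
                kwargs[key] = tuple(kwargs[key])
        profile[block] = cls(**kwargs)
    return profile


def _choose_folds(folds, bundles):
    """Pick test and validation folds that each contain >= 1 positive scan
    (the selection metric and lesion-level TPR are undefined otherwise)."""
    by_patient: dict = {}
    for b in bundles:
        by_patient.setdefault(b.patient_id, []).append(b)

    def fold_bundles(fold):
        return [b for pid in fold for b in by_patient.get(pid, [])]

    def has_pos(fold):
        return any(b.has_cels for b in fold_bundles(fold))

    order = [i for i in range(len(folds)) if has_pos(folds[i])]
    if len(order) < 2:
        raise ValueError("cohort needs >= 2 folds containing CEL-positive scans")
    test_i, val_i = order[0], order[1]
    test = fold_bundles(folds[test_i])
    val = fold_bundles(folds[val_i])
    train = [
        b
        for i, fold in enumerate(folds)
        if i not in (test_i, val_i)
        for b in fold_bundles(fold)
    ]
    return train, val, test


def run_end_to_end(profile: dict | str | Path, outdir, compare_losses: bool = False):
    """Generate a cohort, train, and evaluate on the held-out test fold.

    Writes cohort_summary.csv, history.csv, volume_strata.csv (and
    loss_comparison.csv when ``compare_losses``) under ``outdir``; returns
    the report dict.
    """
    if not isinstance(profile, dict):
        profile = load_profile(profile)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = int(profile.get("seed", 0))
    rng = np.random.default_rng(seed)

    bundles = generate_cohort(
        profile["phantom"],
        n_scans=int(profile["cohort"]["n_scans"]),
        n_patients=int(profile["cohort"]["n_patients"]),
        rng=rng,
    )
    manifest = cohort_manifest(bundles)
    summary = summarize_manifest(manifest)
    pd.DataFrame([summary]).to_csv(outdir / "cohort_summary.csv", index=False)
    manifest.to_csv(outdir / "manifest.csv", index=False)

    folds = split_folds(manifest["patient_id"].tolist(), profile["train"].n_folds, rng)
    train_b, val_b, test_b = _choose_folds(folds, bundles)
    # patient-level leakage check is part of the pipeline, not just a test
    sets = [
        {b.patient_id for b in part} for part in (train_b, val_b, test_b)
    ]
    assert not (sets[0] & sets[1] or sets[0] & sets[2] or sets[1] & sets[2]), (
        "patient leakage across folds"
    )

    def run_training(loss_name: str):
        tc = copy.copy(profile["train"])
        tc.loss = loss_name
        model, history = train_fold(
            train_b,
            val_b,
            network=profile["network"],
            sampling=profile["sampling"],
            loss_config=profile["loss"],
            train_config=tc,
            rng=np.random.default_rng(seed + 1),
        )
        _, _, rep, strata = evaluate_bundles(model, test_b, profile["sampling"])
        return model, history, rep, strata

    model, history, report, strata = run_training(profile["train"].loss)
    from .network import save_checkpoint

    save_checkpoint(
        outdir / "model.ckpt", model, {"sampling": profile["sampling"], "seed": seed}
    )
    history.to_csv(outdir / "history.csv", index=False)
    strata.to_csv(outdir / "volume_strata.csv", index=False)
    report["n_train"] = len(train_b)
    report["n_val"] = len(val_b)
    report["n_test"] = len(test_b)
    report["best_val_dsc"] = history.attrs.get("best_dsc", float("nan"))
    report["seed"] = seed

    if compare_losses:
        other = "starting" if profile["train"].loss == "weighted" else "weighted"
        _, _, rep2, _ = run_training(other)
        comp = pd.DataFrame(
            [
                {"loss": profile["train"].loss, **report},
                {"loss": other, **rep2},
            ]
        )
        comp.to_csv(outdir / "loss_comparison.csv", index=False)
        report["comparison"] = {other: rep2}

    pd.DataFrame(
        [{k: v for k, v in report.items() if not isinstance(v, dict)}]
    ).to_csv(outdir / "report.csv", index=False)
    return report


# ---- loss-direction experiment -------------------------------------------


def compare_losses_on_patches(
    bundles,
    network: NetworkConfig,
    sampling: SamplingConfig,
    loss_config: LossConfig,
    steps: int = 60,
    lr: float = 1e-3,
    batch_size: int = 8,
    seed: int = 0,
):
    """Train the same initialization with the starting vs the weighted loss
    on one fixed imbalanced patch set; returns per-loss mean Dice over the
    positive patches (hard masks at threshold 0.5)."""
    rng = np.random.default_rng(seed)
    norm = [normalize_bundle(b) for b in bundles]
    patches = _epoch_patches(norm, sampling, rng)
    flags = np.array([p.is_positive for p in patches])
    if not flags.any():
        raise ValueError("patch set contains no positive patch")
    try:
        rate = compute_rate_imbalance(flags)
    except ValueError:
        rate = loss_config.rate_imbalance
    lc = LossConfig(
        gamma=loss_config.gamma,
        dice_weight_starting=loss_config.dice_weight_starting,
        rate_imbalance=max(rate, 1.0),
        epsilon=loss_config.epsilon,
        eq5_literal=loss_config.eq5_literal,
    )
    x_all = np.stack([p.channels for p in patches])
    g_all = np.stack([p.gt[None] for p in patches]).astype(np.float64)

    results = {}
    for loss_name in ("starting", "weighted"):
        model = build_model(network, np.random.default_rng(seed + 100))
        opt = nn.Adam(model.parameters(), lr=lr)
        order_rng = np.random.default_rng(seed + 200)
        n = len(patches)
        for step in range(steps):
            idx = order_rng.choice(n, size=min(batch_size, n), replace=False)
            x = nn.Tensor(x_all[idx])
            g = nn.Tensor(g_all[idx])
            pred = model(x)
            if loss_name == "weighted":
                loss = weighted_loss(pred, g, flags[idx], lc)
            else:
                loss = starting_loss(pred, g, lc)
            opt.zero_grad()
            loss.backward()
            opt.step()
        pos_idx = np.flatnonzero(flags)
        dscs = []
        for i in pos_idx:
            prob = model(nn.Tensor(x_all[i : i + 1])).data[0, 0]
            dscs.append(dice_coefficient(prob >= 0.5, g_all[i, 0] > 0.5))
        results[loss_name] = float(np.nanmean(dscs))
    return results
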