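"""Experiment orchestration: centralized training, two-step validation, reports.

Validation follows the two-step protocol used for all training modes:

* step 1 (during training): fixed-size patches from the validation cases
  are scored with the training loss and per-region Dice of the thresholded
  predictions — cheap enough to run every epoch/round;
* step 2 (after training): whole-image validation — each case is cropped to
  its brain bounding box, zero-padded to the network's pooling multiple,
  predicted, unpadded, thresholded at 0.5, reconstructed into a {0,1,2,4}
  label map, and scored per region (DSC, sensitivity, specificity, HD95)
  against the full ground truth.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .augment import AugmentConfig, augment
from .federation import ClientState, FedConfig, run_federation
from .metrics import evaluate_regions
from .model import ModelConfig, UNet3D, WeightSet, build_model
from .nn import Adam
from .phantoms import Case, CohortSplit
from .preprocess import (
    brain_bounding_box,
    crop,
    normalize_volume,
    pad_for_inference,
    random_patch,
    unpad,
)
from .regions import (
    REGION_NAMES,
    DiceLossSpec,
    binarize,
    dice_loss_grad,
    labels_to_regions,
    regions_to_labels,
)

__all__ = [
    "TrainConfig",
    "RunManifest",
    "prepare_training_pairs",
    "train_centralized",
    "validate_patchwise",
    "validate_whole_image",
    "compare_runs",
]


@dataclass(frozen=True)
class TrainConfig:
    """Centralized-training hyperparameters (shared stack with federation)."""

    epochs: int = 300
    eta: float = 1e-4
    batch: int = 1
    patch_shape: tuple[int, int, int] = (32, 32, 32)
    threshold: float = 0.5
    seed: int = 0


@dataclass
class RunManifest:
    """Everything needed to replay a run with the same software version."""

    mode: str
    model_cfg: dict
    train_cfg: dict
    seeds: dict
    split: dict
    outputs: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(dataclasses.asdict(self), indent=2))


def prepare_training_pairs(
    cases: list[Case],
    patch_shape: tuple[int, int, int],
    rng: np.random.Generator,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Normalize, crop each case to its brain extent, extract one patch.

    The order mirrors the preprocessing protocol: per-channel normalization,
    brain-bounding-box crop, then random re-cropping (with symmetric zero
    padding when the brain is smaller than the patch) to ``patch_shape``.
    """
    pairs = []
    for case in cases:
        vol = normalize_volume(case.volume)
        box = brain_bounding_box(vol)
        vol_c, lab_c = crop(vol, case.labels, box)
        pairs.append(random_patch(vol_c, lab_c, patch_shape, rng))
    return pairs


def validate_patchwise(
    weights: WeightSet,
    val_pairs,
    model: UNet3D,
    loss_spec: DiceLossSpec = DiceLossSpec(),
    threshold: float = 0.5,
) -> tuple[float, dict[str, float]]:
    """Step-1 validation: mean loss and per-region Dice on fixed patches."""
    if not val_pairs:
        raise ValueError("validation set is empty")
    model.set_weights(weights)
    losses, dices = [], {name: [] for name in REGION_NAMES}
    for volume, labels in val_pairs:
        truth = labels_to_regions(labels)
        probs = model.forward(volume)
        loss, _ = dice_loss_grad(probs, truth, loss_spec)
        losses.append(loss)
        pred = binarize(probs, threshold)
        for i, name in enumerate(REGION_NAMES):
            inter = (pred[i] * truth[i]).sum()
            denom = pred[i].sum() + truth[i].sum()
            dices[name].append(1.0 if denom == 0 else 2 * inter / denom)
    return float(np.mean(losses)), {k: float(np.mean(v)) for k, v in dices.items()}


def train_centralized(
    cfg: TrainConfig,
    cohort: list[Case],
    split: CohortSplit,
    model_cfg: ModelConfig = ModelConfig(),
    augment_cfg: AugmentConfig | None = None,
    loss_spec: DiceLossSpec = DiceLossSpec(),
    progress=None,
) -> tuple[WeightSet, list[dict]]:
    """Single-site training of the same model/loss/augmentation stack.

    Validates every epoch on the split's validation cases; returns the final
    weights and a per-epoch history (train loss, validation loss, per-region
    validation Dice).  A persistent Adam state spans all epochs.
    """
    by_id = {c.id: c for c in cohort}
    rng = np.random.default_rng(cfg.seed)
    train_pairs = prepare_training_pairs(
        [by_id[i] for i in split.train_ids], cfg.patch_shape, rng
    )
    val_pairs = prepare_training_pairs(
        [by_id[i] for i in split.val_ids], cfg.patch_shape, rng
    )
    if not train_pairs:
        raise ValueError("no training cases")

    model, _ = build_model(model_cfg)
    opt = Adam(lr=cfg.eta)
    params = model.param_views()
    history = []
    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(len(train_pairs))
        losses = []
        model.zero_grads()
        pending = 0
        for idx in order:
            volume, labels = train_pairs[idx]
            if augment_cfg is not None:
                volume, labels = augment(volume, labels, augment_cfg, rng)
            probs = model.forward(volume)
            loss, grad = dice_loss_grad(probs, labels_to_regions(labels), loss_spec)
            losses.append(loss)
            model.backward(grad)
            pending += 1
            if pending == cfg.batch:
                if cfg.batch > 1:
                    for g in model.get_grads().values():
                        g /= cfg.batch
                opt.step(params, model.get_grads())
                model.zero_grads()
                pending = 0
        if pending:
            opt.step(params, model.get_grads())
            model.zero_grads()
        weights = model.get_weights()
        val_loss, val_dice = validate_patchwise(
            weights, val_pairs, model, loss_spec, cfg.threshold
        )
        entry = {
            "epoch": epoch,
            "train_loss": float(np.mean(losses)),
            "val_loss": val_loss,
            **{f"dice_{k}": v for k, v in val_dice.items()},
        }
        history.append(entry)
        if progress is not None:
            progress(entry)
        model.set_weights(weights)
    return model.get_weights(), history


def validate_whole_image(
    weights: WeightSet | None,
    cases: list[Case],
    model_cfg: ModelConfig = ModelConfig(),
    threshold: float = 0.5,
    predict_fn=None,
    pad_multiple: int | None = None,
) -> pd.DataFrame:
    """Step-2 whole-image validation; one row per (case, region).

    ``predict_fn(padded_volume, context)``, when given, replaces the network
    (context carries the case, crop box and pad record) — used to verify the
    geometry pipeline with oracle probabilities.  ``pad_multiple`` overrides
    the zero-padding granularity (default: the network's pooling multiple,
    2^depth); padding to the training patch size instead keeps the
    zero-border fraction, and hence the normalization statistics, matched
    between training and inference.  Means over cases are in the rows with
    ``case_id == "mean"`` (NaN HD95 excluded).
    """
    if not cases:
        raise ValueError("no cases to validate")
    model = None
    if predict_fn is None:
        model, _ = build_model(model_cfg)
        model.set_weights(weights)
    multiple = pad_multiple or 2**model_cfg.depth
    rows = []
    for case in cases:
        vol = normalize_volume(case.volume)
        box = brain_bounding_box(vol)
        vol_c, _ = crop(vol, None, box)
        vol_p, pad_record = pad_for_inference(vol_c, multiple)
        if predict_fn is not None:
            probs = predict_fn(
                vol_p, {"case": case, "box": box, "pad": pad_record}
            )
        else:
            probs = model.forward(vol_p)
        probs = unpad(probs, pad_record)
        pred_labels_crop = regions_to_labels(binarize(probs, threshold))
        pred_labels = np.zeros_like(case.labels)
        pred_labels[box.slices] = pred_labels_crop
        report = evaluate_regions(
            labels_to_regions(pred_labels),
            labels_to_regions(case.labels),
            spacing=case.spacing,
        )
        for region, vals in report.items():
            rows.append({"case_id": case.id, "region": region, **vals})
    df = pd.DataFrame(rows)
    means = (
        df.groupby("region", sort=False)
        .agg({"dsc": "mean", "sensitivity": "mean", "specificity": "mean",
              "hd95": lambda s: float(np.nanmean(s)) if s.notna().any() else np.nan})
        .reset_index()
    )
    means.insert(0, "case_id", "mean")
    return pd.concat([df, means], ignore_index=True)


def compare_runs(histories: dict[str, list[dict]]) -> pd.DataFrame:
    """Align metric curves from several runs into one long-form table.

    ``histories`` maps a mode name to its per-epoch/round history (dicts
    with an ``epoch`` or ``epoch_end`` key plus metric columns).  The final
    row per mode is flagged in the ``final`` column.
    """
    if len(histories) < 2:
        raise ValueError("need at least two runs to compare")
    frames = []
    for mode, hist in histories.items():
        df = pd.DataFrame(hist)
        if "epoch" not in df.columns and "epoch_end" in df.columns:
            df = df.rename(columns={"epoch_end": "epoch"})
        df.insert(0, "mode", mode)
        df["final"] = False
        if len(df):
            df.loc[df.index[-1], "final"] = True
        frames.append(df)
    return pd.concat(frames, ignore_index=True)
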