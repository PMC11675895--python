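"""Desk-scale federated-vs-centralized experiment on synthetic phantoms.

This is the package's headline computation: a four-client horizontal
federation (shard sizes proportional to 37:50:80:100) training a tiny 3D
U-Net on 32^3 phantoms, compared against centralized training under the
same epoch budget, with whole-image evaluation on held-out phantoms.  The
full-scale study conditions (128^3 patches, 350/420 epochs, the full-width
network) are preserved structurally but scaled to sizes a single CPU
handles in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augment import AugmentConfig
from .federation import ClientState, FedConfig, run_federation
from .model import ModelConfig, UNet3D, WeightSet, build_model
from .phantoms import generate_cohort, split_cohort
from .regions import DiceLossSpec
from .runner import (
    TrainConfig,
    prepare_training_pairs,
    train_centralized,
    validate_patchwise,
    validate_whole_image,
)

__all__ = ["DeskScaleConfig", "run_desk_scale_experiment"]


@dataclass(frozen=True)
class DeskScaleConfig:
    """Scaled-down study conditions: 24 train / 8 val / 2 test phantoms at
    32^3, tiny network (depth 2, 4 base filters), 30 rounds of 3 epochs."""

    n_cases: int = 34
    train_frac: float = 24 / 34
    val_frac: float = 8 / 34
    client_proportions: tuple = (37, 50, 80, 100)
    patch_shape: tuple = (32, 32, 32)
    rounds: int = 30
    epochs_per_round: int = 3
    lr: float = 1e-2
    q_range: tuple = (0.4, 0.5)
    dropout_window: tuple = (50, 150, 10)
    noise_sd_data: float = 1e-2
    noise_sd_model: float = 1e-3
    model: ModelConfig = field(default_factory=lambda: ModelConfig(depth=2, base_filters=4))

    @property
    def total_epochs(self) -> int:
        return self.rounds * self.epochs_per_round


def run_desk_scale_experiment(
    seed: int = 0,
    modes=("centralized", "full", "partial"),
    cfg: DeskScaleConfig = DeskScaleConfig(),
    augment: bool = True,
    progress=None,
) -> dict:
    """Train the requested modes under one shared cohort/split and evaluate.

    Returns ``{"split": ..., "modes": {mode: {"history": ..., "report":
    DataFrame, "summary": {region: {metric: value}}}}}``.  The summary holds
    the whole-image validation means on the held-out validation phantoms.
    """
    rng = np.random.default_rng(seed)
    cohort = generate_cohort(cfg.n_cases, seed=int(rng.integers(0, 2**31 - 1)))
    split = split_cohort(
        [c.id for c in cohort],
        train_frac=cfg.train_frac,
        val_frac=cfg.val_frac,
        client_proportions=cfg.client_proportions,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    by_id = {c.id: c for c in cohort}
    val_cases = [by_id[i] for i in split.val_ids]
    aug_cfg = AugmentConfig() if augment else None
    loss_spec = DiceLossSpec()
    mode_seeds = {m: int(rng.integers(0, 2**31 - 1)) for m in ("centralized", "full", "partial")}

    results: dict = {"split": split, "modes": {}}
    for mode in modes:
        if mode == "centralized":
            tc = TrainConfig(
                epochs=cfg.total_epochs,
                eta=cfg.lr,
                patch_shape=cfg.patch_shape,
                seed=mode_seeds[mode],
            )
            weights, history = train_centralized(
                tc, cohort, split, model_cfg=cfg.model,
                augment_cfg=aug_cfg, loss_spec=loss_spec, progress=progress,
            )
        elif mode in ("full", "partial"):
            weights, history = _run_federated(
                mode, cfg, cohort, split, aug_cfg, loss_spec,
                seed=mode_seeds[mode], progress=progress,
            )
        else:
            raise ValueError(f"unknown mode {mode!r}")
        report = validate_whole_image(
            weights, val_cases, model_cfg=cfg.model,
            pad_multiple=cfg.patch_shape[0],
        )
        means = report[report.case_id == "mean"].set_index("region")
        summary = {
            region: {
                "dsc": float(means.loc[region, "dsc"]),
                "sensitivity": float(means.loc[region, "sensitivity"]),
                "specificity": float(means.loc[region, "specificity"]),
                "hd95": float(means.loc[region, "hd95"]),
            }
            for region in means.index
        }
        results["modes"][mode] = {
            "weights": weights,
            "history": history,
            "report": report,
            "summary": summary,
        }
    return results


def _run_federated(mode, cfg, cohort, split, aug_cfg, loss_spec, seed, progress=None):
    by_id = {c.id: c for c in cohort}
    prep_rng = np.random.default_rng(seed)
    clients = []
    for cid, shard in enumerate(split.client_partition):
        pairs = prepare_training_pairs(
            [by_id[i] for i in shard], cfg.patch_shape, prep_rng
        )
        clients.append(ClientState(id=cid, cases=pairs))
    val_pairs = prepare_training_pairs(
        [by_id[i] for i in split.val_ids], cfg.patch_shape, prep_rng
    )
    fed_cfg = FedConfig(
        K=len(clients),
        E=cfg.epochs_per_round,
        eta=cfg.lr,
        total_epochs=cfg.total_epochs,
        q_range=cfg.q_range,
        dropout_window=cfg.dropout_window,
        noise_sd_data=cfg.noise_sd_data,
        noise_sd_model=cfg.noise_sd_model,
        mode=mode,
        seed=seed,
    )
    val_model = UNet3D(cfg.model)

    def validate_fn(weights: WeightSet):
        return validate_patchwise(weights, val_pairs, val_model, loss_spec)

    history, weights = run_federation(
        fed_cfg, cfg.model, clients,
        augment_cfg=aug_cfg, loss_spec=loss_spec,
        validate_fn=validate_fn, progress=progress,
    )
    return weights, history
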