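"""Stochastic training-time augmentations for multi-contrast 3D patches.

Five transforms, applied in a fixed order each call so that runs replay
exactly from a seed:

1. per-channel intensity rescale by one factor ~ U(0.9, 1.1), p = 0.8;
2. per-channel intensity shift by one constant ~ U(-0.1, 0.1), p = 0.1;
3. additive centered Gaussian voxel noise, sd 0.1 (applied with
   probability ``noise_p``, default 1.0);
4. channel dropping: with p = 0.16 one channel, chosen uniformly, is zeroed;
5. independent flips along each spatial axis, p = 0.8 per axis, applied
   identically to the label map.

Only the flips touch the labels; intensity transforms never do.  Rescale
and shift draw one scalar per channel — the channel is the unit of those
transforms, a per-voxel draw would be indistinguishable from noise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["AugmentConfig", "augment", "estimate_application_rates"]


@dataclass(frozen=True)
class AugmentConfig:
    rescale_range: tuple[float, float] = (0.9, 1.1)
    rescale_p: float = 0.8
    shift_range: tuple[float, float] = (-0.1, 0.1)
    shift_p: float = 0.1
    noise_sd: float = 0.1
    noise_p: float = 1.0
    channel_drop_p: float = 0.16
    flip_p: float = 0.8
    seed: int = 0

    def __post_init__(self):
        for p in (self.rescale_p, self.shift_p, self.noise_p, self.channel_drop_p, self.flip_p):
            if not 0 <= p <= 1:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.rescale_range[0] > self.rescale_range[1]:
            raise ValueError("rescale_range must be ordered")
        if self.shift_range[0] > self.shift_range[1]:
            raise ValueError("shift_range must be ordered")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def augment(
    patch: np.ndarray,
    labels: np.ndarray,
    cfg: AugmentConfig,
    rng: np.random.Generator,
    _applied: dict | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Apply the augmentation stack to one (patch, labels) pair.

    ``_applied``, when given, collects which transforms fired (used by the
    calibration harness).  The input arrays are never modified.
    """
    if patch.shape[-3:] != labels.shape:
        raise ValueError("patch and labels are not aligned")
    out = np.array(patch, dtype=np.float64, copy=True)
    lab = labels.copy()
    n_ch = out.shape[0]
    applied = {"rescale": False, "shift": False, "noise": False, "channel_drop": False,
               "flip_axis0": False, "flip_axis1": False, "flip_axis2": False}

    if rng.random() < cfg.rescale_p:
        factors = rng.uniform(*cfg.rescale_range, size=n_ch)
        out *= factors.reshape(-1, 1, 1, 1)
        applied["rescale"] = True
    if rng.random() < cfg.shift_p:
        shifts = rng.uniform(*cfg.shift_range, size=n_ch)
        out += shifts.reshape(-1, 1, 1, 1)
        applied["shift"] = True
    if cfg.noise_p > 0 and rng.random() < cfg.noise_p:
        if cfg.noise_sd > 0:
            out += rng.normal(0.0, cfg.noise_sd, size=out.shape)
        applied["noise"] = True
    if rng.random() < cfg.channel_drop_p:
        out[int(rng.integers(0, n_ch))] = 0.0
        applied["channel_drop"] = True
    for axis in range(3):
        if rng.random() < cfg.flip_p:
            out = np.flip(out, axis=axis + 1)
            lab = np.flip(lab, axis=axis)
            applied[f"flip_axis{axis}"] = True

    if _applied is not None:
        _applied.update(applied)
    return np.ascontiguousarray(out), np.ascontiguousarray(lab)


def estimate_application_rates(
    cfg: AugmentConfig, n_draws: int, patch_shape=(4, 4, 4), seed: int | None = None
) -> dict[str, float]:
    """Empirical per-transform application frequency over ``n_draws`` calls.

    Test harness for the configured probabilities: repeated augmentation of a
    fixed tiny patch, counting which transforms fired.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    patch = np.ones((4,) + tuple(patch_shape))
    labels = np.zeros(patch_shape, dtype=np.int16)
    counts: dict[str, int] = {}
    for _ in range(n_draws):
        fired: dict[str, bool] = {}
        augment(patch, labels, cfg, rng, _applied=fired)
        for k, v in fired.items():
            counts[k] = counts.get(k, 0) + int(v)
    return {k: v / n_draws for k, v in counts.items()}
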