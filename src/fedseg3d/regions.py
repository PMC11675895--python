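"""Label-map ↔ tumor-region encoding and the soft Dice training loss.

The network predicts the three overlapping evaluation regions directly
rather than the individual annotation labels:

* ET (enhancing tumor)  = label 4
* TC (tumor core)       = labels {1, 4}
* WT (whole tumor)      = labels {1, 2, 4}

This mapping is the standard BraTS region composition.  The loss is a soft
Dice accumulated per channel over the whole batch:

    L = 1 - (1/N) * sum_n (2 * sum S_n R_n + eps) / (sum S_n^2 + sum R_n^2 + eps)

with eps = 1 for stability.  A ``verbatim`` variant omitting the factor 2
in the numerator is provided as well; that form cannot reach 0 for a
perfect prediction (for an all-ones 8-voxel channel it evaluates to
1 - 9/17) and exists for comparison, not training.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "REGION_NAMES",
    "DiceLossSpec",
    "labels_to_regions",
    "dice_loss",
    "dice_loss_grad",
    "binarize",
    "regions_to_labels",
]

REGION_NAMES = ("ET", "TC", "WT")


@dataclass(frozen=True)
class DiceLossSpec:
    epsilon: float = 1.0
    variant: str = "standard"  # or "verbatim" (no factor 2 in the numerator)

    def __post_init__(self):
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.variant not in ("standard", "verbatim"):
            raise ValueError("variant must be 'standard' or 'verbatim'")


def labels_to_regions(labels: np.ndarray) -> np.ndarray:
    """Encode a {0,1,2,4} label map as a binary (ET, TC, WT) region tensor."""
    labels = np.asarray(labels)
    bad = set(np.unique(labels)) - {0, 1, 2, 4}
    if bad:
        raise ValueError(f"unknown label values {sorted(bad)}")
    et = labels == 4
    tc = (labels == 1) | et
    wt = (labels == 2) | tc
    return np.stack([et, tc, wt]).astype(np.float64)


def _channel_sums(pred: np.ndarray, truth: np.ndarray):
    """Per-channel cross/s2/r2 sums pooled over the batch.

    Accepts (C, X, Y, Z) or (B, C, X, Y, Z); the batch axis pools into the
    same per-channel sums ("per-batch, per-channel" accumulation).
    """
    pred = np.asarray(pred, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    if pred.ndim == 4:
        pred, truth = pred[None], truth[None]
    axes = (0, 2, 3, 4)
    cross = (pred * truth).sum(axis=axes)
    s2 = (pred**2).sum(axis=axes)
    r2 = (truth**2).sum(axis=axes)
    return cross, s2, r2


def dice_loss(pred: np.ndarray, truth: np.ndarray, spec: DiceLossSpec = DiceLossSpec()) -> float:
    """Region-composed soft Dice loss; 0 iff the prediction is perfect
    (standard variant, binary prediction)."""
    cross, s2, r2 = _channel_sums(pred, truth)
    factor = 2.0 if spec.variant == "standard" else 1.0
    terms = (factor * cross + spec.epsilon) / (s2 + r2 + spec.epsilon)
    return float(1.0 - terms.mean())


def dice_loss_grad(
    pred: np.ndarray, truth: np.ndarray, spec: DiceLossSpec = DiceLossSpec()
) -> tuple[float, np.ndarray]:
    """Loss value and its gradient with respect to the predicted probabilities.

    d/dS of -(1/N)(f*cross+eps)/(s2+r2+eps) per channel:
        -(1/N) * [f*R*(s2+r2+eps) - (f*cross+eps)*2S] / (s2+r2+eps)^2
    """
    pred64 = np.asarray(pred, dtype=np.float64)
    truth64 = np.asarray(truth, dtype=np.float64)
    cross, s2, r2 = _channel_sums(pred64, truth64)
    factor = 2.0 if spec.variant == "standard" else 1.0
    denom = s2 + r2 + spec.epsilon
    numer = factor * cross + spec.epsilon
    loss = float(1.0 - (numer / denom).mean())
    n = cross.shape[0]
    shape = (1, -1, 1, 1, 1) if pred64.ndim == 5 else (-1, 1, 1, 1)
    grad = -(
        factor * truth64 * denom.reshape(shape) - numer.reshape(shape) * 2.0 * pred64
    ) / (n * (denom**2).reshape(shape))
    return loss, grad


def binarize(probs: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Threshold probabilities to a binary region tensor; ties (== threshold)
    go to 1."""
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    return (np.asarray(probs) >= threshold).astype(np.float64)


def regions_to_labels(binary: np.ndarray) -> np.ndarray:
    """Reconstruct a {0,1,2,4} label map from a binary (ET, TC, WT) tensor.

    Nesting is repaired first (TC := TC ∨ ET, WT := WT ∨ TC) so inconsistent
    voxels resolve deterministically, then: ET → 4, TC\\ET → 1, WT\\TC → 2.
    """
    b = np.asarray(binary).astype(bool)
    et, tc, wt = b[0], b[1] | b[0], b[2] | b[1] | b[0]
    labels = np.zeros(et.shape, dtype=np.int16)
    labels[wt & ~tc] = 2
    labels[tc & ~et] = 1
    labels[et] = 4
    return labels
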