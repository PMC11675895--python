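"""Per-region segmentation metrics: DSC, sensitivity, specificity, HD95.

Voxel-count metrics follow the usual confusion-matrix definitions:

    DSC         = 2 TP / (2 TP + FP + FN)
    sensitivity = TP / (TP + FN)
    specificity = TN / (TN + FP)

with the both-empty / empty-denominator conventions documented on each
function (needed for batch evaluation of cases where a region is absent).

HD95 is the 95th percentile (linear interpolation) of the pooled
bidirectional surface-to-surface distance set, in millimetres.  Surfaces
are mask voxels with at least one face-adjacent (6-connected) background
neighbour, counting everything outside the array as background.  The
pooled estimator is symmetric by construction and matches common BraTS
evaluation tooling; a max-of-directed-percentiles alternative is exposed
via ``pooled=False``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .regions import REGION_NAMES

__all__ = [
    "ConfusionCounts",
    "confusion_counts",
    "dsc",
    "sensitivity",
    "specificity",
    "surface_mask",
    "hd95",
    "evaluate_regions",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def confusion_counts(pred: np.ndarray, truth: np.ndarray) -> ConfusionCounts:
    """Voxelwise confusion tabulation of two binary masks."""
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp, fp, fn, tn)


def dsc(c: ConfusionCounts) -> float:
    """Dice similarity coefficient; 1.0 when both masks are empty."""
    denom = 2 * c.tp + c.fp + c.fn
    return 1.0 if denom == 0 else 2 * c.tp / denom


def sensitivity(c: ConfusionCounts) -> float:
    """True-positive rate; 1.0 by convention when the truth has no positives."""
    denom = c.tp + c.fn
    return 1.0 if denom == 0 else c.tp / denom


def specificity(c: ConfusionCounts) -> float:
    """True-negative rate; 1.0 by convention when the truth has no negatives."""
    denom = c.tn + c.fp
    return 1.0 if denom == 0 else c.tn / denom


def surface_mask(mask: np.ndarray) -> np.ndarray:
    """Mask voxels with >= 1 face-adjacent background neighbour.

    Voxels on the array border count the outside as background.
    """
    mask = np.asarray(mask).astype(bool)
    if not mask.any():
        return np.zeros_like(mask)
    footprint = ndimage.generate_binary_structure(3, 1)  # 6-connectivity
    eroded = ndimage.binary_erosion(mask, structure=footprint, border_value=0)
    return mask & ~eroded


def hd95(
    pred: np.ndarray,
    truth: np.ndarray,
    spacing=(1.0, 1.0, 1.0),
    pooled: bool = True,
) -> float:
    """95th-percentile Hausdorff distance between two binary masks, in mm.

    Directed distances run from each surface voxel of one mask to the
    nearest surface voxel of the other (Euclidean, spacing-scaled).  With
    ``pooled=True`` the percentile is taken over both directed lists
    concatenated; otherwise it is the max of the two directed percentiles.

    Conventions: both masks empty → 0.0; exactly one empty → NaN (excluded
    from means, with a warning).
    """
    pred = np.asarray(pred).astype(bool)
    truth = np.asarray(truth).astype(bool)
    if pred.shape != truth.shape:
        raise ValueError("prediction and truth shapes differ")
    p_empty, t_empty = not pred.any(), not truth.any()
    if p_empty and t_empty:
        return 0.0
    if p_empty or t_empty:
        warnings.warn("hd95 undefined: exactly one mask is empty", stacklevel=2)
        return float("nan")
    sp = surface_mask(pred)
    st = surface_mask(truth)
    # distance field to the other surface, sampled at this surface's voxels
    dist_to_t = ndimage.distance_transform_edt(~st, sampling=spacing)
    dist_to_p = ndimage.distance_transform_edt(~sp, sampling=spacing)
    d_pt = dist_to_t[sp]
    d_tp = dist_to_p[st]
    if pooled:
        return float(np.percentile(np.concatenate([d_pt, d_tp]), 95))
    return float(max(np.percentile(d_pt, 95), np.percentile(d_tp, 95)))


def evaluate_regions(
    pred_regions: np.ndarray, truth_regions: np.ndarray, spacing=(1.0, 1.0, 1.0)
) -> dict[str, dict[str, float]]:
    """Full metric report per region for one case.

    Both inputs are binary (ET, TC, WT) tensors; returns
    ``{region: {dsc, sensitivity, specificity, hd95}}``.
    """
    report = {}
    for i, name in enumerate(REGION_NAMES):
        c = confusion_counts(pred_regions[i], truth_regions[i])
        report[name] = {
            "dsc": dsc(c),
            "sensitivity": sensitivity(c),
            "specificity": specificity(c),
            "hd95": hd95(pred_regions[i], truth_regions[i], spacing=spacing),
        }
    return report
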