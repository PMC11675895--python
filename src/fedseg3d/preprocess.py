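"""Volume preprocessing: percentile clipping, normalization, cropping, patching.

Conventions fixed once and used everywhere:

* all boxes are 0-based, half-open ``[start, stop)`` per axis;
* percentiles use linear interpolation over the sorted nonzero values;
* min-max scaling uses the post-clip channel min/max (zeros included), so
  the background stays exactly 0 — the brain bounding box and the phantom
  invariants rely on that.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "BoundingBox",
    "clip_normalize_channel",
    "normalize_volume",
    "brain_bounding_box",
    "crop",
    "random_patch",
    "pad_for_inference",
    "unpad",
]


@dataclass(frozen=True)
class BoundingBox:
    """Half-open per-axis voxel index ranges."""

    start: tuple[int, int, int]
    stop: tuple[int, int, int]

    def __post_init__(self):
        for a, b in zip(self.start, self.stop):
            if not 0 <= a < b:
                raise ValueError("box must satisfy 0 <= start < stop")

    @property
    def slices(self) -> tuple[slice, slice, slice]:
        return tuple(slice(a, b) for a, b in zip(self.start, self.stop))

    @property
    def shape(self) -> tuple[int, int, int]:
        return tuple(b - a for a, b in zip(self.start, self.stop))


def clip_normalize_channel(channel: np.ndarray) -> np.ndarray:
    """Clip one channel to the 1st/99th percentiles of its nonzero voxels,
    then min-max scale to [0, 1].

    Percentiles are computed over strictly nonzero voxels only; the min-max
    bounds are the post-clip min and max of the whole channel (zeros
    included).  An all-zero channel is returned unchanged; a channel whose
    post-clip dynamic range is zero maps to all zeros.
    """
    channel = np.asarray(channel, dtype=np.float64)
    nz = channel[channel != 0]
    if nz.size == 0:
        return channel.copy()
    p1, p99 = np.percentile(nz, [1, 99])
    out = np.clip(channel, p1, p99)
    lo, hi = out.min(), out.max()
    if hi == lo:
        return np.zeros_like(out)
    return (out - lo) / (hi - lo)


def normalize_volume(volume: np.ndarray) -> np.ndarray:
    """Apply ``clip_normalize_channel`` to each contrast channel independently."""
    return np.stack([clip_normalize_channel(ch) for ch in volume])


def brain_bounding_box(volume: np.ndarray) -> BoundingBox:
    """Tightest box containing every voxel nonzero in any channel.

    Falls back to the full-volume box when the volume is entirely zero.
    """
    spatial = volume.shape[-3:]
    fg = (np.asarray(volume) != 0).any(axis=0) if volume.ndim == 4 else volume != 0
    if not fg.any():
        return BoundingBox((0, 0, 0), spatial)
    idx = np.nonzero(fg)
    start = tuple(int(i.min()) for i in idx)
    stop = tuple(int(i.max()) + 1 for i in idx)
    return BoundingBox(start, stop)


def crop(
    volume: np.ndarray, labels: np.ndarray | None, box: BoundingBox
) -> tuple[np.ndarray, np.ndarray | None]:
    """Crop volume (and labels, if given) to ``box``; identical geometry."""
    spatial = volume.shape[-3:]
    for a, b, n in zip(box.start, box.stop, spatial):
        if b > n:
            raise ValueError("box exceeds volume extent")
    sl = box.slices
    v = volume[(...,) + sl]
    l = labels[sl] if labels is not None else None
    return v.copy(), None if l is None else l.copy()


def _pad_widths(shape, target):
    widths = []
    for n, t in zip(shape, target):
        extra = max(t - n, 0)
        widths.append((extra // 2, extra - extra // 2))
    return widths


def random_patch(
    volume: np.ndarray,
    labels: np.ndarray,
    patch_shape: tuple[int, int, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Extract a uniform-random patch of exactly ``patch_shape``.

    Axes smaller than the patch are first zero-padded symmetrically (content
    centered, extra voxel on the high side); the random corner is then drawn
    uniformly per axis.
    """
    if any(p <= 0 for p in patch_shape):
        raise ValueError("patch_shape must be positive")
    spatial = volume.shape[-3:]
    widths = _pad_widths(spatial, patch_shape)
    if any(w != (0, 0) for w in widths):
        volume = np.pad(volume, [(0, 0)] + widths)
        labels = np.pad(labels, widths)
        spatial = volume.shape[-3:]
    corner = tuple(int(rng.integers(0, n - p + 1)) for n, p in zip(spatial, patch_shape))
    sl = tuple(slice(c, c + p) for c, p in zip(corner, patch_shape))
    return volume[(...,) + sl].copy(), labels[sl].copy()


def pad_for_inference(
    volume: np.ndarray, multiple: int
) -> tuple[np.ndarray, list[tuple[int, int]]]:
    """Zero-pad each spatial axis up to the next multiple (for pooling depth).

    Returns the padded array and the exact per-axis padding applied, which
    ``unpad`` inverts.
    """
    if multiple < 1:
        raise ValueError("multiple must be >= 1")
    spatial = volume.shape[-3:]
    target = [int(np.ceil(n / multiple)) * multiple for n in spatial]
    widths = _pad_widths(spatial, target)
    lead = [(0, 0)] * (volume.ndim - 3)
    return np.pad(volume, lead + widths), widths


def unpad(array: np.ndarray, pad_record: list[tuple[int, int]]) -> np.ndarray:
    """Exact inverse of ``pad_for_inference``."""
    spatial = array.shape[-3:]
    sl = []
    for (lo, hi), n in zip(pad_record, spatial):
        if lo + hi >= n:
            raise ValueError("pad record does not match array shape")
        sl.append(slice(lo, n - hi))
    return array[(...,) + tuple(sl)].copy()
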