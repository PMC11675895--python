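"""Synthetic multi-modal brain phantoms with nested tumor compartments.

Each phantom emulates the structure of a multi-institutional glioma MRI
case: four contrast channels (T1, T1Gd, T2, FLAIR), a brain foreground of
nonzero intensities on an exactly-zero background, and an integer label map
over {0, 1, 2, 4} (NCR/NET = 1, edema = 2, enhancing tumor = 4) with the
nested geometry the evaluation regions assume: the enhancing core sits
inside the tumor core, which is surrounded by an edema shell.

Geometry is deliberately simple — concentric spheres inside an axis-aligned
ellipsoid — which is the smallest shape family guaranteeing ET ⊂ TC ⊂ WT by
construction.  Intensities are not claimed anatomically realistic; the four
channels get distinct tissue-contrast orderings so channel-level operations
(normalization, channel dropping) have observable effects.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "PhantomSpec",
    "Case",
    "CohortSplit",
    "generate_case",
    "generate_cohort",
    "split_cohort",
    "make_folds",
    "largest_remainder",
    "default_spec_sampler",
    "save_cohort_nifti",
    "load_cohort_nifti",
]

#: tissue row order used by ``channel_contrasts``
TISSUES = ("brain", "ncr_net", "edema", "enhancing")

#: channel (modality) order of every phantom volume
MODALITIES = ("t1", "t1gd", "t2", "flair")

# Mean intensity per (modality, tissue) pair.  Orderings differ per channel:
# enhancing tumor is brightest on T1Gd, edema brightest on FLAIR/T2, the
# core dark on T1 — enough contrast structure for a network to learn from.
DEFAULT_CONTRASTS = np.array(
    [
        # brain  ncr/net  edema  enhancing
        [0.60, 0.30, 0.50, 0.55],  # t1
        [0.50, 0.35, 0.45, 0.95],  # t1gd
        [0.45, 0.55, 0.80, 0.60],  # t2
        [0.40, 0.50, 0.90, 0.55],  # flair
    ]
)


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one synthetic case.

    ``region_radii`` are the (ET, TC, WT) sphere radii in voxels and must be
    strictly increasing; the WT sphere must fit inside the brain ellipsoid.
    """

    volume_shape: tuple[int, int, int] = (32, 32, 32)
    brain_radius_frac: float = 0.45
    tumor_center: tuple[float, float, float] = (16.0, 16.0, 16.0)
    region_radii: tuple[float, float, float] = (3.0, 5.0, 8.0)
    channel_contrasts: np.ndarray = field(
        default_factory=lambda: DEFAULT_CONTRASTS.copy()
    )
    noise_sd: float = 0.05
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.volume_shape):
            raise ValueError("volume_shape must be positive")
        r_et, r_tc, r_wt = self.region_radii
        if not (0 < r_et < r_tc < r_wt):
            raise ValueError("region_radii must be strictly increasing and > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        cc = np.asarray(self.channel_contrasts, dtype=float)
        if cc.shape != (4, 4):
            raise ValueError("channel_contrasts must be a 4x4 table")
        # tumor sphere must lie inside the brain ellipsoid:
        # max over the surface of the normalized ellipsoid coordinate <= 1
        semi = self._brain_semiaxes()
        c = np.asarray(self.tumor_center, float)
        center = (np.asarray(self.volume_shape, float) - 1) / 2.0
        # sufficient condition: |c - center|/a + r_wt/a_min <= 1 per axis norm
        u = np.linalg.norm((c - center) / semi)
        if u + r_wt / semi.min() > 1.0:
            raise ValueError("whole-tumor sphere does not fit inside the brain")

    def _brain_semiaxes(self) -> np.ndarray:
        return self.brain_radius_frac * np.asarray(self.volume_shape, dtype=float)


@dataclass
class Case:
    """One phantom: a 4-channel intensity volume plus its label map."""

    id: str
    volume: np.ndarray  # (4, X, Y, Z) float
    labels: np.ndarray  # (X, Y, Z) int, values in {0,1,2,4}
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)

    def validate(self) -> None:
        if self.volume.ndim != 4 or self.volume.shape[0] != 4:
            raise ValueError("volume must have shape (4, X, Y, Z)")
        if self.volume.shape[1:] != self.labels.shape:
            raise ValueError("volume and labels spatial shapes differ")
        bad = set(np.unique(self.labels)) - {0, 1, 2, 4}
        if bad:
            raise ValueError(f"unexpected label values {sorted(bad)}")
        fg = (self.volume != 0).any(axis=0)
        if np.any((self.labels > 0) & ~fg):
            raise ValueError("tumor voxels outside the brain foreground")


def _masks(spec: PhantomSpec):
    shape = spec.volume_shape
    grid = np.indices(shape, dtype=float)
    center = (np.asarray(shape, float) - 1) / 2.0
    semi = spec._brain_semiaxes()
    brain = (((grid - center.reshape(3, 1, 1, 1)) / semi.reshape(3, 1, 1, 1)) ** 2).sum(
        axis=0
    ) <= 1.0
    d = np.sqrt(
        ((grid - np.asarray(spec.tumor_center, float).reshape(3, 1, 1, 1)) ** 2).sum(
            axis=0
        )
    )
    r_et, r_tc, r_wt = spec.region_radii
    return brain, d <= r_et, d <= r_tc, d <= r_wt


def generate_case(spec: PhantomSpec, case_id: str = "case-0000") -> Case:
    """Render one phantom from its spec; deterministic given ``spec.seed``."""
    brain, et, tc, wt = _masks(spec)
    labels = np.zeros(spec.volume_shape, dtype=np.int16)
    labels[wt] = 2
    labels[tc] = 1
    labels[et] = 4

    # tissue index per voxel: 0 brain, 1 ncr/net, 2 edema, 3 enhancing
    tissue = np.full(spec.volume_shape, -1, dtype=np.int8)
    tissue[brain] = 0
    tissue[labels == 2] = 2
    tissue[labels == 1] = 1
    tissue[labels == 4] = 3

    rng = np.random.default_rng(spec.seed)
    cc = np.asarray(spec.channel_contrasts, dtype=float)
    volume = np.zeros((4,) + tuple(spec.volume_shape), dtype=np.float64)
    inside = tissue >= 0
    for ch in range(4):
        means = cc[ch][tissue[inside]]
        noisy = means + rng.normal(0.0, spec.noise_sd, size=means.shape)
        # keep the foreground strictly nonzero so background-0 semantics hold
        volume[ch][inside] = np.maximum(noisy, 1e-6)

    case = Case(id=case_id, volume=volume, labels=labels, spacing=spec.spacing)
    case.validate()
    return case


def default_spec_sampler(rng: np.random.Generator, base: PhantomSpec | None = None) -> PhantomSpec:
    """Draw a per-case spec: tumor position and radii vary, geometry stays valid."""
    base = base or PhantomSpec()
    shape = np.asarray(base.volume_shape, float)
    center = (shape - 1) / 2.0
    for _ in range(100):
        r_et = rng.uniform(1.5, 3.0)
        r_tc = r_et + rng.uniform(1.0, 2.5)
        r_wt = r_tc + rng.uniform(1.5, 3.5)
        offset = rng.uniform(-0.12, 0.12, size=3) * shape
        try:
            return replace(
                base,
                tumor_center=tuple(center + offset),
                region_radii=(r_et, r_tc, r_wt),
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        except ValueError:
            continue
    raise RuntimeError("could not sample a valid phantom spec")


def generate_cohort(
    n_cases: int,
    spec_sampler=default_spec_sampler,
    seed: int = 0,
) -> list[Case]:
    """Generate ``n_cases`` phantoms with varying tumor position/size."""
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    rng = np.random.default_rng(seed)
    cases = []
    for i in range(n_cases):
        spec = spec_sampler(rng)
        cases.append(generate_case(spec, case_id=f"case-{i:04d}"))
    return cases


def largest_remainder(total: int, proportions) -> list[int]:
    """Integer apportionment of ``total`` by the largest-remainder method."""
    p = np.asarray(proportions, dtype=float)
    if np.any(p <= 0):
        raise ValueError("proportions must be positive")
    quotas = total * p / p.sum()
    sizes = np.floor(quotas).astype(int)
    short = total - sizes.sum()
    # stable tie-break: larger remainder first, then lower index
    order = sorted(range(len(p)), key=lambda i: (-(quotas[i] - sizes[i]), i))
    for i in order[:short]:
        sizes[i] += 1
    return sizes.tolist()


@dataclass
class CohortSplit:
    """Train/val/test ids plus the per-client shards of the training ids."""

    train_ids: list[str]
    val_ids: list[str]
    test_ids: list[str]
    client_partition: list[list[str]]

    def validate(self) -> None:
        pools = [set(self.train_ids), set(self.val_ids), set(self.test_ids)]
        for i in range(3):
            for j in range(i + 1, 3):
                if pools[i] & pools[j]:
                    raise ValueError("train/val/test ids overlap")
        shard_union: set[str] = set()
        total = 0
        for shard in self.client_partition:
            s = set(shard)
            if shard_union & s:
                raise ValueError("client shards overlap")
            shard_union |= s
            total += len(shard)
        if shard_union != set(self.train_ids) or total != len(self.train_ids):
            raise ValueError("client shards must exactly cover the training ids")


def split_cohort(
    case_ids,
    train_frac: float = 267 / 369,
    val_frac: float = 66 / 369,
    client_proportions=(37, 50, 80, 100),
    seed: int = 0,
) -> CohortSplit:
    """Shuffle, cut into train/val/test, shard the train set across clients.

    Client sizes follow largest-remainder apportionment of the train count by
    ``client_proportions``; with 267 training cases and proportions
    37:50:80:100 the shards are exactly 37, 50, 80 and 100 cases.
    """
    if not (0 < train_frac < 1 and 0 < val_frac < 1 and train_frac + val_frac < 1):
        raise ValueError("fractions must be in (0,1) and sum to < 1")
    ids = list(case_ids)
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    n = len(ids)
    n_train = int(round(n * train_frac))
    n_val = int(round(n * val_frac))
    train, val, test = ids[:n_train], ids[n_train : n_train + n_val], ids[n_train + n_val :]
    if len(train) < len(client_proportions):
        raise ValueError("fewer training cases than clients")
    sizes = largest_remainder(len(train), client_proportions)
    shards, at = [], 0
    for s in sizes:
        shards.append(train[at : at + s])
        at += s
    split = CohortSplit(train, val, test, shards)
    split.validate()
    return split


def make_folds(case_ids, k: int, seed: int = 0) -> list[list[str]]:
    """Shuffle and deal ids into ``k`` folds whose sizes differ by at most 1."""
    if k < 2:
        raise ValueError("k must be >= 2")
    ids = list(case_ids)
    if len(ids) < k:
        raise ValueError("need at least k ids")
    rng = np.random.default_rng(seed)
    rng.shuffle(ids)
    return [ids[i::k] for i in range(k)]


# ---------------------------------------------------------------------------
# optional NIfTI round-trip

def save_cohort_nifti(cases: list[Case], out_dir: str | Path) -> Path:
    """Write each case as <id>_img.nii.gz / <id>_seg.nii.gz plus a manifest."""
    import nibabel as nib

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {}
    for case in cases:
        affine = np.diag(list(case.spacing) + [1.0])
        img = nib.Nifti1Image(
            np.moveaxis(case.volume, 0, -1).astype(np.float32), affine
        )
        seg = nib.Nifti1Image(case.labels.astype(np.int16), affine)
        img_p, seg_p = out / f"{case.id}_img.nii.gz", out / f"{case.id}_seg.nii.gz"
        nib.save(img, img_p)
        nib.save(seg, seg_p)
        manifest[case.id] = {"image": img_p.name, "labels": seg_p.name}
    mpath = out / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=2))
    return mpath


def load_cohort_nifti(manifest_path: str | Path) -> list[Case]:
    import nibabel as nib

    mpath = Path(manifest_path)
    manifest = json.loads(mpath.read_text())
    cases = []
    for cid, paths in manifest.items():
        img = nib.load(mpath.parent / paths["image"])
        seg = nib.load(mpath.parent / paths["labels"])
        spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
        cases.append(
            Case(
                id=cid,
                volume=np.moveaxis(np.asarray(img.dataobj, dtype=np.float64), -1, 0),
                labels=np.asarray(seg.dataobj, dtype=np.int16),
                spacing=spacing,
            )
        )
    return cases
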