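"""Configurable encoder-decoder 3D segmentation network (U-Net family).

The architecture follows the standard contracting/expanding pattern: each
encoder stage is a convolutional block (two 3x3x3 convolutions, each with
group normalization and ReLU) followed by 2x max pooling; filter counts
double per stage.  The decoder mirrors it with 2x2x2 transposed-convolution
upsampling and skip concatenation, ending in a 1x1x1 convolution with a
sigmoid that emits one probability map per tumor region (ET, TC, WT).

Depth and width are configurable: the ``tiny`` preset (depth 2, 4 base
filters) is sized for CPU-scale federation experiments; ``full-scale``
mirrors a full-size variant structurally but is not meant to be trained
here.  Weights initialize he-normal from a seed, so two builds from the
same config are bit-identical.

A model's parameters travel as a :class:`WeightSet` — an ordered mapping of
qualified layer names to arrays — which is the unit the federation engine
aggregates.
"""

from __future__ import annotations

from collections import OrderedDict
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .augment import AugmentConfig, augment
from .nn import Adam, Conv3d, ConvTranspose3d, GroupNorm, MaxPool3d, ReLU, Sigmoid
from .regions import DiceLossSpec, dice_loss_grad, labels_to_regions

__all__ = [
    "ModelConfig",
    "WeightSet",
    "UNet3D",
    "build_model",
    "forward",
    "train_local",
    "MODEL_PRESETS",
]


@dataclass(frozen=True)
class ModelConfig:
    in_channels: int = 4
    out_channels: int = 3
    depth: int = 2
    base_filters: int = 4
    groups: int = 4
    seed: int = 0

    def __post_init__(self):
        if self.depth < 1 or self.base_filters < 1:
            raise ValueError("depth and base_filters must be >= 1")
        for i in range(self.depth + 1):
            if (self.base_filters * 2**i) % self.groups:
                raise ValueError(
                    f"groups={self.groups} must divide stage filters "
                    f"{self.base_filters * 2**i}"
                )


MODEL_PRESETS = {
    "tiny": ModelConfig(depth=2, base_filters=4, groups=4),
    "full-scale": ModelConfig(depth=4, base_filters=16, groups=8),
}


class WeightSet(OrderedDict):
    """Ordered mapping of qualified parameter names to numeric arrays."""

    def copy(self) -> "WeightSet":
        return WeightSet((k, v.copy()) for k, v in self.items())

    def map(self, fn) -> "WeightSet":
        return WeightSet((k, fn(v)) for k, v in self.items())

    def allclose(self, other: "WeightSet", **kw) -> bool:
        return list(self) == list(other) and all(
            np.allclose(self[k], other[k], **kw) for k in self
        )

    def save(self, path: str | Path) -> None:
        np.savez(path, **self)

    @classmethod
    def load(cls, path: str | Path) -> "WeightSet":
        with np.load(path) as z:
            return cls((k, z[k]) for k in z.files)


class _ConvBlock:
    def __init__(self, cin, cout, groups, rng):
        self.layers = [
            Conv3d(cin, cout, 3, rng),
            GroupNorm(cout, groups),
            ReLU(),
            Conv3d(cout, cout, 3, rng),
            GroupNorm(cout, groups),
            ReLU(),
        ]

    def forward(self, x):
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def backward(self, g):
        for layer in reversed(self.layers):
            g = layer.backward(g)
        return g


class UNet3D:
    """Single-sample 3D U-Net with explicit forward/backward passes."""

    def __init__(self, cfg: ModelConfig):
        self.cfg = cfg
        rng = np.random.default_rng(cfg.seed)
        f = cfg.base_filters
        self.enc, self.pools, self.ups, self.dec = [], [], [], []
        cin = cfg.in_channels
        for i in range(cfg.depth):
            self.enc.append(_ConvBlock(cin, f * 2**i, cfg.groups, rng))
            self.pools.append(MaxPool3d())
            cin = f * 2**i
        self.bottleneck = _ConvBlock(cin, f * 2**cfg.depth, cfg.groups, rng)
        for i in reversed(range(cfg.depth)):
            self.ups.append(ConvTranspose3d(f * 2 ** (i + 1), f * 2**i, rng))
            self.dec.append(_ConvBlock(f * 2 ** (i + 1), f * 2**i, cfg.groups, rng))
        self.final = Conv3d(f, cfg.out_channels, 1, rng)
        self.sigmoid = Sigmoid()
        self._register()

    # -- parameter registry ------------------------------------------------
    def _register(self):
        reg: "OrderedDict[str, tuple]" = OrderedDict()
        for i, blk in enumerate(self.enc):
            for j, layer in enumerate(blk.layers):
                for key in layer.params:
                    reg[f"enc{i}.{j}.{key}"] = (layer, key)
        for j, layer in enumerate(self.bottleneck.layers):
            for key in layer.params:
                reg[f"bottleneck.{j}.{key}"] = (layer, key)
        for i, (up, blk) in enumerate(zip(self.ups, self.dec)):
            for key in up.params:
                reg[f"up{i}.{key}"] = (up, key)
            for j, layer in enumerate(blk.layers):
                for key in layer.params:
                    reg[f"dec{i}.{j}.{key}"] = (layer, key)
        for key in self.final.params:
            reg[f"final.{key}"] = (self.final, key)
        self._registry = reg

    def get_weights(self) -> WeightSet:
        return WeightSet((k, layer.params[key].copy()) for k, (layer, key) in self._registry.items())

    def set_weights(self, ws: WeightSet) -> None:
        for k, (layer, key) in self._registry.items():
            layer.params[key][...] = ws[k]

    def zero_grads(self) -> None:
        for layer, _ in self._registry.values():
            layer.zero_grads()

    def get_grads(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict(
            (k, layer.grads[key]) for k, (layer, key) in self._registry.items()
        )

    def param_views(self) -> "OrderedDict[str, np.ndarray]":
        return OrderedDict(
            (k, layer.params[key]) for k, (layer, key) in self._registry.items()
        )

    # -- passes ------------------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        d = self.cfg.depth
        for n in x.shape[1:]:
            if n % 2**d:
                raise ValueError(
                    f"spatial extent {n} not divisible by 2^depth={2**d}; "
                    "pad_for_inference first"
                )
        skips = []
        h = np.asarray(x, dtype=np.float64)
        for blk, pool in zip(self.enc, self.pools):
            h = blk.forward(h)
            skips.append(h)
            h = pool.forward(h)
        h = self.bottleneck.forward(h)
        self._skip_channels = []
        for up, dec, skip in zip(self.ups, self.dec, reversed(skips)):
            h = up.forward(h)
            self._skip_channels.append(skip.shape[0])
            h = dec.forward(np.concatenate([skip, h], axis=0))
        return self.sigmoid.forward(self.final.forward(h))

    def backward(self, gout: np.ndarray) -> None:
        g = self.final.backward(self.sigmoid.backward(gout))
        skip_grads = []
        for up, dec, c_skip in zip(
            reversed(self.ups), reversed(self.dec), reversed(self._skip_channels)
        ):
            g = dec.backward(g)
            skip_grads.append(g[:c_skip])
            g = up.backward(g[c_skip:])
        g = self.bottleneck.backward(g)
        # skip_grads[i] is the gradient w.r.t. encoder stage i's output;
        # the encoder backward walks stages deepest-first
        for blk, pool, gs in zip(
            reversed(self.enc), reversed(self.pools), reversed(skip_grads)
        ):
            g = pool.backward(g)
            g = blk.backward(g + gs)


def build_model(cfg: ModelConfig) -> tuple[UNet3D, WeightSet]:
    """Construct the network and return it with its initial WeightSet."""
    model = UNet3D(cfg)
    return model, model.get_weights()


def forward(model: UNet3D, volume: np.ndarray) -> np.ndarray:
    """Predict (ET, TC, WT) probability maps for one preprocessed volume."""
    return model.forward(volume)


def train_local(
    model: UNet3D,
    weights: WeightSet,
    cases,
    epochs: int,
    lr: float = 1e-4,
    batch: int = 1,
    augment_cfg: AugmentConfig | None = None,
    loss_spec: DiceLossSpec = DiceLossSpec(),
    rng: np.random.Generator | None = None,
) -> tuple[WeightSet, list[float]]:
    """Run local epochs of Adam on soft Dice loss; returns updated weights.

    ``cases`` is a sequence of (volume, labels) pairs already preprocessed to
    the training patch size.  Each epoch reshuffles the cases (both an
    optimization and a privacy measure: the model never sees a fixed data
    order).  The input ``weights`` are copied, never modified.  Gradients
    accumulate over ``batch`` consecutive samples before each optimizer step
    (the default, batch 1, steps per sample).

    Returns the new WeightSet and the per-epoch mean training loss.
    """
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    cases = list(cases)
    if not cases:
        raise ValueError("empty training dataset")
    rng = rng or np.random.default_rng(0)
    model.set_weights(weights)
    opt = Adam(lr=lr)
    params = model.param_views()
    history = []
    for _ in range(epochs):
        order = rng.permutation(len(cases))
        losses = []
        model.zero_grads()
        pending = 0
        for idx in order:
            volume, labels = cases[idx]
            if augment_cfg is not None:
                volume, labels = augment(volume, labels, augment_cfg, rng)
            truth = labels_to_regions(labels)
            probs = model.forward(volume)
            loss, grad = dice_loss_grad(probs, truth, loss_spec)
            losses.append(loss)
            model.backward(grad)
            pending += 1
            if pending == batch:
                if batch > 1:
                    grads = model.get_grads()
                    for g in grads.values():
                        g /= batch
                opt.step(params, model.get_grads())
                model.zero_grads()
                pending = 0
        if pending:
            opt.step(params, model.get_grads())
            model.zero_grads()
        history.append(float(np.mean(losses)))
    return model.get_weights(), history
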