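"""Federated training engine: FedAvg, partial weight sharing, DP noise, dropout.

The simulator runs the classic federated loop in process, sequentially over
clients: the server broadcasts the global WeightSet, each participating
client trains locally for E epochs, perturbs its update with differential-
privacy noise, and transmits either its full weights (``full`` mode, plain
sample-size-weighted FedAvg) or a sparsified copy (``partial`` mode) in
which only a random fraction q of positions per layer survive and the rest
are sent as zeros.

The partial-sharing server rule, applied independently at every weight
position across the transmitted client tensors:

* all clients zero        → keep the previous global value;
* exactly one nonzero     → take that client's value;
* two or more nonzero     → unweighted mean of the nonzero values;

followed by a final smoothing step: the new global model is the elementwise
simple average of the previous global model and the aggregate above.  The
rule treats "zero" as "not shared"; a trained weight that is exactly 0.0 is
indistinguishable from a masked one, an inherent property of the protocol
(probability zero for continuous weights).

Client dropout: inside a configured epoch window, rounds whose starting
epoch falls on the window period exclude one uniformly chosen client from
both training and aggregation, emulating institutions going offline.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .augment import AugmentConfig
from .model import ModelConfig, UNet3D, WeightSet, build_model, train_local
from .regions import DiceLossSpec

__all__ = [
    "FedConfig",
    "ClientState",
    "ShareMask",
    "RoundRecord",
    "fedavg_aggregate",
    "sample_share_mask",
    "apply_mask",
    "masked_aggregate",
    "add_dp_noise",
    "dropout_participants",
    "run_federation",
]


@dataclass(frozen=True)
class FedConfig:
    """Federation hyperparameters.

    Defaults mirror the study conditions: K=4 clients with every client
    participating (C=1), 3 local epochs per round, batch size 1, learning
    rate 1e-4, a 40-50% sharing fraction in partial mode, and one client
    dropped every 10th epoch inside the 50-150 epoch window.
    """

    K: int = 4
    C: float = 1.0
    E: int = 3
    B: int = 1
    eta: float = 1e-4
    total_epochs: int = 420
    q_range: tuple[float, float] = (0.4, 0.5)
    dropout_window: tuple[int, int, int] = (50, 150, 10)  # start, end, period
    noise_sd_data: float = 1e-2
    noise_sd_model: float = 1e-3
    mode: str = "partial"  # or "full"
    validate_from_epoch: int = 9
    seed: int = 0

    def __post_init__(self):
        if not 0 < self.C <= 1:
            raise ValueError("C must be in (0, 1]")
        if self.E < 1:
            raise ValueError("E must be >= 1")
        lo, hi = self.q_range
        if not 0 < lo <= hi <= 1:
            raise ValueError("q_range must satisfy 0 < lo <= hi <= 1")
        if self.dropout_window[0] > self.dropout_window[1]:
            raise ValueError("dropout window start must be <= end")
        if self.mode not in ("full", "partial"):
            raise ValueError("mode must be 'full' or 'partial'")
        if self.total_epochs % self.E:
            raise ValueError("total_epochs must divide into rounds of E epochs")

    @property
    def n_rounds(self) -> int:
        return self.total_epochs // self.E


@dataclass
class ClientState:
    """One simulated institution: its shard and current local weights."""

    id: int
    cases: list  # list of (volume, labels) training pairs
    n_k: int = 0
    weights: WeightSet | None = None
    augment_seed: int = 0

    def __post_init__(self):
        self.n_k = self.n_k or len(self.cases)
        if self.n_k < 1:
            raise ValueError("client must hold at least one case")


@dataclass
class ShareMask:
    """Per-layer binary masks plus the realized sharing fraction."""

    masks: WeightSet
    q: float
    q_effective: float


@dataclass
class RoundRecord:
    round_index: int
    epoch_start: int
    epoch_end: int
    participants: list[int]
    q_by_client: dict[int, float] = field(default_factory=dict)
    train_loss_by_client: dict[int, float] = field(default_factory=dict)
    val_loss: float | None = None
    val_dice: dict[str, float] | None = None


# ---------------------------------------------------------------------------
# aggregation primitives

def fedavg_aggregate(client_weights: list[WeightSet], n_k: list[int]) -> WeightSet:
    """Sample-size-weighted position-wise mean of the participants' weights."""
    if not client_weights:
        raise ValueError("no client weights to aggregate")
    if len(client_weights) != len(n_k):
        raise ValueError("one sample count per client required")
    n = float(sum(n_k))
    keys = list(client_weights[0])
    out = WeightSet()
    for key in keys:
        acc = np.zeros_like(client_weights[0][key], dtype=np.float64)
        for w, nk in zip(client_weights, n_k):
            if w[key].shape != acc.shape:
                raise ValueError(f"shape mismatch at {key}")
            acc += (nk / n) * w[key]
        out[key] = acc
    return out


def sample_share_mask(
    shapes: dict[str, tuple], q_range: tuple[float, float], rng: np.random.Generator
) -> ShareMask:
    """Draw q ~ U(q_range) and a per-layer uniform random position mask.

    Per layer, round-half-away-from-zero of q*count positions are selected,
    with a minimum of one so every layer contributes to aggregation.
    """
    lo, hi = q_range
    q = float(rng.uniform(lo, hi))
    masks = WeightSet()
    selected = total = 0
    for name, shape in shapes.items():
        count = int(np.prod(shape))
        k = max(1, int(np.floor(q * count + 0.5)))
        k = min(k, count)
        flat = np.zeros(count)
        flat[rng.choice(count, size=k, replace=False)] = 1.0
        masks[name] = flat.reshape(shape)
        selected += k
        total += count
    return ShareMask(masks=masks, q=q, q_effective=selected / total)


def apply_mask(w: WeightSet, m: ShareMask) -> WeightSet:
    """Zero the non-selected positions; the input WeightSet is untouched."""
    out = WeightSet()
    for key, arr in w.items():
        if m.masks[key].shape != arr.shape:
            raise ValueError(f"mask shape mismatch at {key}")
        out[key] = arr * m.masks[key]
    return out


def masked_aggregate(prev_global: WeightSet, shared: list[WeightSet]) -> WeightSet:
    """Partial-sharing server update with the zero-weight rules.

    Per position: all-zero → previous global value; one nonzero → that
    value; several nonzero → their unweighted mean.  The returned global
    model is the elementwise simple average of the previous global model
    and that aggregate.
    """
    if not shared:
        raise ValueError("no shared weights to aggregate")
    out = WeightSet()
    for key, prev in prev_global.items():
        stack = np.stack([w[key] for w in shared])
        if stack.shape[1:] != prev.shape:
            raise ValueError(f"shape mismatch at {key}")
        nonzero = stack != 0
        count = nonzero.sum(axis=0)
        total = (stack * nonzero).sum(axis=0)
        new = np.where(count > 0, total / np.maximum(count, 1), prev)
        out[key] = 0.5 * (prev + new)
    return out


def add_dp_noise(target, sd: float, rng: np.random.Generator):
    """Add centered Gaussian perturbation noise; sd=0 returns an exact copy.

    Applied to each client's training volumes once before training (data-
    level noise) and to each local WeightSet after training, before any
    masking/transmission (model-level noise).
    """
    if sd < 0:
        raise ValueError("sd must be >= 0")
    if isinstance(target, WeightSet):
        if sd == 0:
            return target.copy()
        return target.map(lambda v: v + rng.normal(0.0, sd, size=v.shape))
    arr = np.asarray(target, dtype=np.float64)
    if sd == 0:
        return arr.copy()
    return arr + rng.normal(0.0, sd, size=arr.shape)


def dropout_participants(
    round_epoch_start: int,
    K: int,
    window: tuple[int, int, int],
    rng: np.random.Generator,
) -> list[int]:
    """Participant ids for a round starting at the given global epoch.

    Inside [start, end], rounds whose starting epoch is offset from the
    window start by a multiple of the period lose one uniformly chosen
    client; all K participate otherwise.
    """
    if K < 2:
        raise ValueError("K must be >= 2")
    start, end, period = window
    e = round_epoch_start
    if start <= e <= end and (e - start) % period == 0:
        dropped = int(rng.integers(0, K))
        return [k for k in range(K) if k != dropped]
    return list(range(K))


# ---------------------------------------------------------------------------
# orchestration

def run_federation(
    fed_cfg: FedConfig,
    model_cfg: ModelConfig,
    clients: list[ClientState],
    val_cases=None,
    augment_cfg: AugmentConfig | None = None,
    loss_spec: DiceLossSpec = DiceLossSpec(),
    validate_fn=None,
    progress=None,
) -> tuple[list[RoundRecord], WeightSet]:
    """Run the full federated loop and return (history, final global weights).

    ``clients`` hold preprocessed training pairs; data-level DP noise is
    applied to each client's volumes once, up front.  ``validate_fn``, when
    given, is called as ``validate_fn(weights)`` for rounds whose epoch span
    has reached ``validate_from_epoch`` and must return
    ``(val_loss, {region: dice})``.
    """
    if len(clients) != fed_cfg.K:
        raise ValueError("client list must have exactly K entries")
    rng = np.random.default_rng(fed_cfg.seed)
    model = UNet3D(model_cfg)
    _, global_w = build_model(model_cfg)

    # per-source independent streams, all derived from the run seed
    drop_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    mask_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    noise_rng = np.random.default_rng(rng.integers(0, 2**31 - 1))
    client_rngs = [
        np.random.default_rng(rng.integers(0, 2**31 - 1)) for _ in clients
    ]

    # data-level DP noise: perturb each client's volumes once before training
    noisy_clients = []
    for client in clients:
        cases = [
            (add_dp_noise(vol, fed_cfg.noise_sd_data, noise_rng), lab)
            for vol, lab in client.cases
        ]
        noisy_clients.append(
            ClientState(
                id=client.id, cases=cases, n_k=client.n_k,
                augment_seed=client.augment_seed,
            )
        )

    shapes = {k: v.shape for k, v in global_w.items()}
    history: list[RoundRecord] = []
    for r in range(fed_cfg.n_rounds):
        epoch_start = r * fed_cfg.E + 1
        epoch_end = epoch_start + fed_cfg.E - 1
        participants = dropout_participants(
            epoch_start, fed_cfg.K, fed_cfg.dropout_window, drop_rng
        )
        if fed_cfg.C < 1 and len(participants) > 1:
            m = max(int(round(fed_cfg.C * len(participants))), 1)
            participants = sorted(
                drop_rng.choice(participants, size=m, replace=False).tolist()
            )
        record = RoundRecord(
            round_index=r,
            epoch_start=epoch_start,
            epoch_end=epoch_end,
            participants=list(participants),
        )

        updates, counts = [], []
        for cid in participants:
            client = noisy_clients[cid]
            local_w, losses = train_local(
                model,
                global_w,
                client.cases,
                epochs=fed_cfg.E,
                lr=fed_cfg.eta,
                batch=fed_cfg.B,
                augment_cfg=augment_cfg,
                loss_spec=loss_spec,
                rng=client_rngs[cid],
            )
            record.train_loss_by_client[cid] = losses[-1]
            local_w = add_dp_noise(local_w, fed_cfg.noise_sd_model, noise_rng)
            if fed_cfg.mode == "partial":
                mask = sample_share_mask(shapes, fed_cfg.q_range, mask_rng)
                record.q_by_client[cid] = mask.q
                local_w = apply_mask(local_w, mask)
            updates.append(local_w)
            counts.append(client.n_k)

        if fed_cfg.mode == "partial":
            global_w = masked_aggregate(global_w, updates)
        else:
            global_w = fedavg_aggregate(updates, counts)

        if validate_fn is not None and epoch_end >= fed_cfg.validate_from_epoch:
            record.val_loss, record.val_dice = validate_fn(global_w)
        history.append(record)
        if progress is not None:
            progress(record)
    return history, global_w
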