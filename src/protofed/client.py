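"""Per-client (per-hospital) local training and class-prototype extraction.

Each simulated hospital receives the broadcast global model, trains it for
a fixed number of local epochs on its own shard with Adam (cross-entropy
loss plus an L2 weight penalty realized as weight decay), then extracts
class prototypes — the mean penultimate feature vector of each class it
holds — and reports (trained state, prototypes with support counts, shard
size) back to the server.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .data import LabeledDataset, augment_batch
from .models import ModelState, SkipPlan, TinyCNN, apply_skip_plan, load_state_into_model, state_from_model
from .nn import AdamOptimizer, cross_entropy_grad

__all__ = ["TrainingConfig", "PrototypeSet", "ClientUpdate", "local_train", "extract_prototypes"]


@dataclass(frozen=True)
class TrainingConfig:
    """Local-training hyperparameters.

    Defaults follow the simulator's reference protocol: Adam, learning
    rate 1e-3, weight decay 1e-4 (the L2 coefficient of the regularized
    local objective), batch size 64, 5 local epochs, cross-entropy loss.
    ``align_weight`` adds an optional prototype-alignment penalty pulling
    each sample's features toward the broadcast global prototype of its
    class (off by default). ``augment`` enables random rotation/flip/zoom.
    """

    learning_rate: float = 1e-3
    weight_decay: float = 1e-4
    batch_size: int = 64
    local_epochs: int = 5
    seed: int = 42
    augment: bool = False
    align_weight: float = 0.0

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.weight_decay < 0:
            raise ValueError("rates must be positive")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.local_epochs < 0:
            raise ValueError("local_epochs must be >= 0")

    @classmethod
    def desk_scale(cls, seed: int = 42, **overrides) -> "TrainingConfig":
        """Training configuration calibrated for the scratch NumPy CNN on
        the synthetic motif data (learning rate 1e-2).

        The 1e-3 default of the plain constructor matches the reference
        fine-tuning protocol for large pretrained backbones; a CNN trained
        from scratch for a handful of epochs needs the larger step size.
        """
        overrides.setdefault("learning_rate", 1e-2)
        return cls(seed=seed, **overrides)


@dataclass
class PrototypeSet:
    """Per-class (prototype vector, support count); absent classes omitted."""

    prototypes: dict[int, np.ndarray] = field(default_factory=dict)
    counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.prototypes) != set(self.counts):
            raise ValueError("prototype and count keys must match")
        if any(n < 1 for n in self.counts.values()):
            raise ValueError("support counts must be >= 1")

    @property
    def total_count(self) -> int:
        return sum(self.counts.values())

    def feature_width(self) -> int | None:
        for v in self.prototypes.values():
            return int(v.size)
        return None

    def copy(self) -> "PrototypeSet":
        return PrototypeSet(
            {c: v.copy() for c, v in self.prototypes.items()}, dict(self.counts)
        )


@dataclass
class ClientUpdate:
    """What one client sends back after a round of local training."""

    client_id: int
    model_state: ModelState
    prototypes: PrototypeSet
    n_samples: int

    def __post_init__(self) -> None:
        if self.n_samples != self.prototypes.total_count:
            raise ValueError("n_samples must equal the prototype support total")


def local_train(
    global_state: ModelState,
    plan: SkipPlan,
    shard: LabeledDataset,
    cfg: TrainingConfig,
    global_prototypes: PrototypeSet | None = None,
    input_stats: tuple[float, float] = (0.5, 0.25),
    client_id: int = 0,
) -> ClientUpdate:
    """Train the broadcast model on one client's shard.

    The model is initialized from ``global_state``, the skip plan's groups
    are frozen (and returned bit-identical), and exactly
    ``cfg.local_epochs`` passes over the shard are run with seeded batch
    shuffling. Prototypes are extracted from the final local model.
    """
    if len(shard) == 0:
        raise ValueError("client shard is empty")
    x = shard.pixel_array()
    y = shard.labels
    if y.min() < 0 or y.max() >= global_state.num_classes:
        raise ValueError("shard labels outside the model's class range")

    model = TinyCNN(global_state.num_classes, in_channels=x.shape[1], input_stats=input_stats)
    load_state_into_model(model, global_state)
    apply_skip_plan(model, plan)

    opt = AdamOptimizer(lr=cfg.learning_rate, weight_decay=cfg.weight_decay)
    rng = np.random.default_rng([cfg.seed, client_id])
    n = len(shard)
    use_align = (
        cfg.align_weight > 0
        and global_prototypes is not None
        and len(global_prototypes.prototypes) > 0
    )
    for _ in range(cfg.local_epochs):
        order = rng.permutation(n)
        for start in range(0, n, cfg.batch_size):
            sel = order[start : start + cfg.batch_size]
            xb, yb = x[sel], y[sel]
            if cfg.augment:
                xb = augment_batch(xb, rng)
            logits = model.forward(xb, train=True)
            _, dlogits = cross_entropy_grad(logits, yb)
            dfeats = None
            if use_align:
                feats = model._cache["feats"]
                target = np.stack(
                    [
                        global_prototypes.prototypes.get(int(c), feats[i])
                        for i, c in enumerate(yb)
                    ]
                )
                dfeats = 2.0 * cfg.align_weight * (feats - target) / len(yb)
            grads = model.backward(dlogits, dfeats_extra=dfeats)
            opt.step(model, grads)

    protos = extract_prototypes(model, shard)
    return ClientUpdate(client_id, state_from_model(model), protos, n)


def extract_prototypes(model: TinyCNN, shard: LabeledDataset) -> PrototypeSet:
    """Class prototypes: the arithmetic mean of pooled penultimate features
    over each class's samples, with the class support count."""
    if len(shard) == 0:
        raise ValueError("cannot extract prototypes from an empty shard")
    x = shard.pixel_array()
    y = shard.labels
    feats = model.features(x)
    protos: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for c in np.unique(y):
        mask = y == c
        protos[int(c)] = feats[mask].mean(axis=0)
        counts[int(c)] = int(mask.sum())
    return PrototypeSet(protos, counts)
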