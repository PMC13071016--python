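"""Model registry: backbones, layer inventories, skip plans and state export.

Two tiers of architectures are registered:

* ``tiny_cnn`` — a fully trainable, deterministic NumPy CNN (see
  :mod:`protofed.nn`) used for all desk-scale simulation and tests.
* ``resnet50``, ``efficientnet_b0``, ``convnext``, ``swin`` — large ImageNet
  backbones registered with *exact analytic layer inventories*: per-stage
  parameter counts computed from the published topologies (including batch /
  layer norm parameters and the classifier head resized to ``num_classes``).
  These inventories drive skip planning and communication-cost accounting;
  the simulator does not instantiate or train them.

Layer skipping freezes whole parameter groups, earliest-first in forward
order (the transfer-learning convention: early layers carry generic
features), until the frozen fraction reaches the requested skip ratio.
The classifier head is never frozen.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .nn import TinyCNN

__all__ = [
    "LayerInventory",
    "SkipPlan",
    "ModelState",
    "ARCHITECTURES",
    "build_model",
    "layer_inventory",
    "total_params",
    "make_skip_plan",
    "apply_skip_plan",
    "extract_features",
    "state_from_model",
    "load_state_into_model",
    "save_checkpoint",
    "load_checkpoint",
    "UnsupportedArchitectureError",
]

ARCHITECTURES = ("tiny_cnn", "resnet50", "efficientnet_b0", "convnext", "swin")


class UnsupportedArchitectureError(ValueError):
    """Raised for registry names that cannot be instantiated as trainable models."""


@dataclass(frozen=True)
class LayerInventory:
    """Ordered (group_name, parameter_count, is_classifier_head) in forward order."""

    groups: tuple[tuple[str, int, bool], ...]

    def __post_init__(self) -> None:
        heads = [g for g in self.groups if g[2]]
        if len(heads) != 1 or not self.groups[-1][2]:
            raise ValueError("exactly one classifier head, and it must be last")
        if any(n <= 0 for _, n, _ in self.groups):
            raise ValueError("parameter counts must be positive")

    @property
    def total_params(self) -> int:
        return sum(n for _, n, _ in self.groups)

    @property
    def head_params(self) -> int:
        return self.groups[-1][1]

    def names(self) -> list[str]:
        return [g for g, _, _ in self.groups]


@dataclass(frozen=True)
class SkipPlan:
    """Which parameter groups are frozen at a given skip ratio."""

    skip_ratio: float
    frozen_groups: frozenset[str]
    total_params: int
    trainable_params: int

    def __post_init__(self) -> None:
        if not 0.0 <= self.skip_ratio < 1.0:
            raise ValueError("skip_ratio must be in [0, 1)")


@dataclass
class ModelState:
    """Named map group_name -> flat float64 parameter vector."""

    arch: str
    num_classes: int
    groups: dict[str, np.ndarray]

    def flatten(self, order: list[str] | None = None) -> np.ndarray:
        names = order or list(self.groups)
        return np.concatenate([np.asarray(self.groups[g], dtype=np.float64) for g in names])

    def copy(self) -> "ModelState":
        return ModelState(self.arch, self.num_classes, {g: v.copy() for g, v in self.groups.items()})

    @staticmethod
    def unflatten(
        flat: np.ndarray, template: "ModelState", order: list[str] | None = None
    ) -> "ModelState":
        names = order or list(template.groups)
        out: dict[str, np.ndarray] = {}
        pos = 0
        for g in names:
            n = template.groups[g].size
            out[g] = flat[pos : pos + n].copy()
            pos += n
        if pos != flat.size:
            raise ValueError("flat vector length does not match template")
        return ModelState(template.arch, template.num_classes, out)


# ---------------------------------------------------------------------------
# analytic inventories of the large backbones
# ---------------------------------------------------------------------------


def _resnet50_inventory(num_classes: int) -> LayerInventory:
    """ResNet50 v1 parameter accounting: 7x7 stem, bottleneck stages
    [3, 4, 6, 3], batch norm after every convolution, no convolution biases,
    linear head 2048 -> num_classes."""

    def bottleneck(cin: int, width: int, downsample: bool) -> int:
        p = cin * width + 2 * width          # 1x1 reduce + BN
        p += 9 * width * width + 2 * width   # 3x3 + BN
        p += width * 4 * width + 8 * width   # 1x1 expand + BN
        if downsample:
            p += cin * 4 * width + 8 * width  # projection shortcut + BN
        return p

    groups: list[tuple[str, int, bool]] = [("stem", 3 * 64 * 49 + 2 * 64, False)]
    cin = 64
    for i, (width, reps) in enumerate([(64, 3), (128, 4), (256, 6), (512, 3)], start=1):
        tot = bottleneck(cin, width, True)
        tot += (reps - 1) * bottleneck(4 * width, width, False)
        groups.append((f"stage{i}", tot, False))
        cin = 4 * width
    groups.append(("head", 2048 * num_classes + num_classes, True))
    return LayerInventory(tuple(groups))


def _efficientnet_b0_inventory(num_classes: int) -> LayerInventory:
    """EfficientNet-B0 accounting: MBConv stages with squeeze-excitation
    (squeeze width = block input channels / 4), 1x1 head conv to 1280."""

    def mbconv(cin: int, cout: int, expand: int, k: int) -> int:
        mid = cin * expand
        p = 0
        if expand != 1:
            p += cin * mid + 2 * mid            # expand 1x1 + BN
        p += mid * k * k + 2 * mid              # depthwise + BN
        s = max(1, cin // 4)                    # SE squeeze width
        p += mid * s + s + s * mid + mid        # SE 1x1 convs with biases
        p += mid * cout + 2 * cout              # project 1x1 + BN
        return p

    cfg = [  # (expand, out_channels, repeats, kernel)
        (1, 16, 1, 3), (6, 24, 2, 3), (6, 40, 2, 5), (6, 80, 3, 3),
        (6, 112, 3, 5), (6, 192, 4, 5), (6, 320, 1, 3),
    ]
    groups: list[tuple[str, int, bool]] = [("stem", 3 * 32 * 9 + 2 * 32, False)]
    cin = 32
    for i, (e, cout, reps, k) in enumerate(cfg, start=1):
        tot = mbconv(cin, cout, e, k)
        tot += (reps - 1) * mbconv(cout, cout, e, k)
        groups.append((f"stage{i}", tot, False))
        cin = cout
    groups.append(("features_top", 320 * 1280 + 2 * 1280, False))
    groups.append(("head", 1280 * num_classes + num_classes, True))
    return LayerInventory(tuple(groups))


def _convnext_tiny_inventory(num_classes: int) -> LayerInventory:
    """ConvNeXt-Tiny accounting: depths (3,3,9,3), dims (96,192,384,768),
    7x7 depthwise + two pointwise linears + layer scale per block."""

    def block(d: int) -> int:
        return (49 * d + d) + 2 * d + (d * 4 * d + 4 * d) + (4 * d * d + d) + d

    dims = (96, 192, 384, 768)
    depths = (3, 3, 9, 3)
    groups: list[tuple[str, int, bool]] = [
        ("stem", 3 * 96 * 16 + 96 + 2 * 96, False)  # 4x4 patchify conv + LN
    ]
    for i, (d, n) in enumerate(zip(dims, depths), start=1):
        tot = n * block(d)
        if i < 4:  # downsample layer: LN + 2x2 stride-2 conv
            tot += 2 * d + d * 2 * d * 4 + 2 * d
        groups.append((f"stage{i}", tot, False))
    groups.append(("head", 2 * 768 + 768 * num_classes + num_classes, True))
    return LayerInventory(tuple(groups))


def _swin_tiny_inventory(num_classes: int) -> LayerInventory:
    """Swin-Tiny accounting: depths (2,2,6,2), dims 96..768, heads (3,6,12,24),
    7x7 windows (169-entry relative-position bias table per head)."""

    def block(d: int, nh: int) -> int:
        attn = (d * 3 * d + 3 * d) + 169 * nh + (d * d + d)
        mlp = d * 4 * d + 4 * d + 4 * d * d + d
        return 2 * d + attn + 2 * d + mlp

    dims = (96, 192, 384, 768)
    depths = (2, 2, 6, 2)
    heads = (3, 6, 12, 24)
    groups: list[tuple[str, int, bool]] = [
        ("patch_embed", 3 * 96 * 16 + 96 + 2 * 96, False)
    ]
    for i, (d, n, nh) in enumerate(zip(dims, depths, heads), start=1):
        tot = n * block(d, nh)
        if i < 4:  # patch merging: LN(4d) + linear 4d -> 2d (no bias)
            tot += 8 * d + 8 * d * d
        groups.append((f"stage{i}", tot, False))
    groups.append(("head", 2 * 768 + 768 * num_classes + num_classes, True))
    return LayerInventory(tuple(groups))


def _tiny_cnn_inventory(num_classes: int) -> LayerInventory:
    model = TinyCNN(num_classes)
    sizes = model.group_sizes()
    groups = tuple(
        (g, sizes[g], g == "head") for g in TinyCNN.GROUP_ORDER
    )
    return LayerInventory(groups)


_INVENTORIES = {
    "tiny_cnn": _tiny_cnn_inventory,
    "resnet50": _resnet50_inventory,
    "efficientnet_b0": _efficientnet_b0_inventory,
    "convnext": _convnext_tiny_inventory,
    "swin": _swin_tiny_inventory,
}


def layer_inventory(arch_name: str, num_classes: int = 4) -> LayerInventory:
    """Forward-order parameter-group inventory for a registered architecture."""
    if arch_name not in _INVENTORIES:
        raise UnsupportedArchitectureError(
            f"unknown architecture {arch_name!r}; registry: {sorted(_INVENTORIES)}"
        )
    if num_classes < 2:
        raise ValueError("num_classes must be >= 2")
    return _INVENTORIES[arch_name](num_classes)


def total_params(arch_name: str, num_classes: int = 4) -> int:
    return layer_inventory(arch_name, num_classes).total_params


def build_model(
    arch_name: str,
    num_classes: int,
    seed: int = 42,
    input_stats: tuple[float, float] = (0.5, 0.25),
) -> tuple[TinyCNN, ModelState]:
    """Instantiate a trainable model with a ``num_classes``-way head.

    Only ``tiny_cnn`` is instantiable; the large backbones are registered
    inventory-only (use :func:`layer_inventory` for parameter accounting and
    skip/cost planning).
    """
    if arch_name not in _INVENTORIES:
        raise UnsupportedArchitectureError(
            f"unknown architecture {arch_name!r}; registry: {sorted(_INVENTORIES)}"
        )
    if arch_name != "tiny_cnn":
        raise UnsupportedArchitectureError(
            f"{arch_name!r} is registered inventory-only; desk-scale training "
            "uses 'tiny_cnn'"
        )
    model = TinyCNN(num_classes, seed=seed, input_stats=input_stats)
    return model, state_from_model(model)


def state_from_model(model: TinyCNN) -> ModelState:
    return ModelState(
        "tiny_cnn",
        model.num_classes,
        {g: model.get_group_vector(g) for g in TinyCNN.GROUP_ORDER},
    )


def load_state_into_model(model: TinyCNN, state: ModelState) -> TinyCNN:
    if state.arch != "tiny_cnn" or state.num_classes != model.num_classes:
        raise ValueError("state does not match model architecture")
    for g in TinyCNN.GROUP_ORDER:
        model.set_group_vector(g, state.groups[g])
    return model


def make_skip_plan(inventory: LayerInventory, skip_ratio: float) -> SkipPlan:
    """Freeze groups greedily in forward order until the frozen parameter
    count reaches ``skip_ratio * total_params``; the head stays trainable."""
    if not 0.0 <= skip_ratio < 1.0:
        raise ValueError("skip_ratio must be in [0, 1); the head must stay trainable")
    total = inventory.total_params
    target = skip_ratio * total
    frozen: list[str] = []
    cum = 0
    for name, n, is_head in inventory.groups:
        if is_head or cum >= target:
            break
        frozen.append(name)
        cum += n
    return SkipPlan(skip_ratio, frozenset(frozen), total, total - cum)


def apply_skip_plan(model: TinyCNN, plan: SkipPlan) -> TinyCNN:
    """Mark the plan's groups frozen on the model (no training updates)."""
    names = set(TinyCNN.GROUP_ORDER)
    unknown = plan.frozen_groups - names
    if unknown or plan.total_params != sum(model.group_sizes().values()):
        raise ValueError(
            f"skip plan does not match model architecture (unknown groups: {sorted(unknown)})"
        )
    model.frozen = set(plan.frozen_groups)
    return model


def extract_features(model: TinyCNN, batch: np.ndarray) -> np.ndarray:
    """Globally pooled penultimate feature vectors for a batch of images."""
    return model.features(batch)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------


def save_checkpoint(state: ModelState, path: str | Path) -> Path:
    """Write a ModelState as ``<path>.npz`` plus a JSON sidecar ``<path>.json``."""
    path = Path(path)
    np.savez(path.with_suffix(".npz"), **state.groups)
    sidecar = {
        "arch": state.arch,
        "num_classes": state.num_classes,
        "groups": {g: int(v.size) for g, v in state.groups.items()},
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2))
    return path.with_suffix(".npz")


def load_checkpoint(path: str | Path) -> ModelState:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    with np.load(path.with_suffix(".npz")) as data:
        groups = {g: data[g].astype(np.float64) for g in meta["groups"]}
    return ModelState(meta["arch"], meta["num_classes"], groups)
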