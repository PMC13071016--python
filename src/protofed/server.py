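"""Federated server: round orchestration, FedAvg and prototype aggregation.

A round broadcasts the global model to every client, runs local training
on each shard, applies the configured privacy mechanisms to the returned
updates (DP clip-and-noise on parameter deltas and prototypes; secure
aggregation by pairwise masking of the weight-scaled states), aggregates
with sample-count-weighted FedAvg, merges class prototypes with the
count-weighted rule, and evaluates the new global model on the shared
held-out test set.

For secure aggregation to commute with weighted averaging, each client's
flattened state is pre-scaled by its FedAvg weight n_k/n before masking;
the server then sums the masked vectors, which equals the weighted mean
exactly because the masks cancel.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .client import ClientUpdate, PrototypeSet, TrainingConfig, local_train
from .costs import per_round_cost
from .data import LabeledDataset, dirichlet_partition
from .metrics import MetricsRow, evaluate_model, rows_to_frame
from .models import (
    ModelState,
    TinyCNN,
    build_model,
    layer_inventory,
    load_state_into_model,
    make_skip_plan,
    total_params,
)
from .privacy import DPConfig, PrivacyMode, SAConfig, clip_and_noise, noise_prototypes, secure_mask

__all__ = [
    "RoundResult",
    "ExperimentConfig",
    "fedavg",
    "aggregate_prototypes",
    "run_round",
    "run_experiment",
    "run_configurations",
]


@dataclass
class RoundResult:
    round_index: int
    global_state: ModelState
    global_prototypes: PrototypeSet
    metrics: MetricsRow
    comm_MB: float  # all clients, this round


@dataclass(frozen=True)
class ExperimentConfig:
    """One federated experiment configuration.

    Defaults mirror the simulator's reference protocol: 5 clients,
    8 rounds, Dirichlet alpha 0.5, seed 42.
    """

    arch: str = "tiny_cnn"
    n_clients: int = 5
    rounds: int = 8
    alpha: float = 0.5
    skip_ratio: float = 0.0
    privacy_mode: PrivacyMode = PrivacyMode.NO_PRIVACY
    dp: DPConfig = field(default_factory=DPConfig)
    sa: SAConfig = field(default_factory=SAConfig)
    training: TrainingConfig = field(default_factory=TrainingConfig)
    seed: int = 42
    prototype_merge: str = "merge"  # "merge" (carry across rounds) or "replace"
    eval_with_prototypes: bool = False

    def __post_init__(self) -> None:
        if self.n_clients < 2:
            raise ValueError("n_clients must be >= 2")
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.prototype_merge not in ("merge", "replace"):
            raise ValueError("prototype_merge must be 'merge' or 'replace'")


def fedavg(updates: list[ClientUpdate]) -> ModelState:
    """Sample-count-weighted average of client model states.

    Every parameter group of the result is sum_k (n_k / n) * state_k.
    """
    if not updates:
        raise ValueError("fedavg needs at least one update")
    names = list(updates[0].model_state.groups)
    for u in updates[1:]:
        if list(u.model_state.groups) != names or any(
            u.model_state.groups[g].size != updates[0].model_state.groups[g].size
            for g in names
        ):
            raise ValueError("client states have mismatched groups")
    n_total = sum(u.n_samples for u in updates)
    if n_total <= 0:
        raise ValueError("total sample count must be positive")
    out = {
        g: sum((u.n_samples / n_total) * u.model_state.groups[g] for u in updates)
        for g in names
    }
    ref = updates[0].model_state
    return ModelState(ref.arch, ref.num_classes, out)


def aggregate_prototypes(proto_sets: list[PrototypeSet]) -> PrototypeSet:
    """Count-weighted per-class prototype aggregation.

    For each class c held by at least one client,
    P(c) = sum_k n_k(c) p_k(c) / sum_k n_k(c); the global support is
    sum_k n_k(c). Classes absent everywhere stay absent.
    """
    if not proto_sets:
        raise ValueError("need at least one prototype set")
    widths = {s.feature_width() for s in proto_sets if s.feature_width() is not None}
    if len(widths) > 1:
        raise ValueError("prototype feature widths differ across clients")
    protos: dict[int, np.ndarray] = {}
    counts: dict[int, int] = {}
    for s in proto_sets:
        for c, p in s.prototypes.items():
            n = s.counts[c]
            if c in protos:
                protos[c] = protos[c] + n * p
                counts[c] += n
            else:
                protos[c] = n * np.asarray(p, dtype=np.float64)
                counts[c] = n
    for c in protos:
        protos[c] = protos[c] / counts[c]
    return PrototypeSet(protos, counts)


def _round_seed(base: int, round_index: int) -> int:
    return int(np.random.SeedSequence([base, round_index]).generate_state(1)[0] % (2**31))


def run_round(
    global_state: ModelState,
    server_prototypes: PrototypeSet,
    cfg: ExperimentConfig,
    shards: dict[int, LabeledDataset],
    test_set: LabeledDataset,
    round_index: int = 0,
    input_stats: tuple[float, float] = (0.5, 0.25),
    dp_rng: np.random.Generator | None = None,
) -> RoundResult:
    """Execute one federated round and evaluate the new global model."""
    inventory = layer_inventory(cfg.arch, global_state.num_classes)
    plan = make_skip_plan(inventory, cfg.skip_ratio)
    train_cfg = replace(cfg.training, seed=_round_seed(cfg.training.seed, round_index))
    if dp_rng is None:
        dp_rng = np.random.default_rng([cfg.dp.seed, round_index])

    updates: list[ClientUpdate] = []
    for cid in sorted(shards):
        try:
            upd = local_train(
                global_state,
                plan,
                shards[cid],
                train_cfg,
                global_prototypes=server_prototypes,
                input_stats=input_stats,
                client_id=cid,
            )
        except Exception as exc:
            raise RuntimeError(f"client {cid} failed in round {round_index}: {exc}") from exc
        updates.append(upd)

    order = list(global_state.groups)
    if cfg.privacy_mode.uses_dp:
        base = global_state.flatten(order)
        noised: list[ClientUpdate] = []
        for u in updates:
            delta = u.model_state.flatten(order) - base
            delta = clip_and_noise(delta, cfg.dp, dp_rng)
            state = ModelState.unflatten(base + delta, global_state, order)
            protos = noise_prototypes(u.prototypes, cfg.dp, dp_rng)
            noised.append(ClientUpdate(u.client_id, state, protos, u.n_samples))
        updates = noised

    if cfg.privacy_mode.uses_sa:
        n_total = sum(u.n_samples for u in updates)
        scaled = {
            u.client_id: (u.n_samples / n_total) * u.model_state.flatten(order)
            for u in updates
        }
        masked = secure_mask(scaled, cfg.sa)
        agg_flat = np.sum([masked[i] for i in sorted(masked)], axis=0)
        new_state = ModelState.unflatten(agg_flat, global_state, order)
    else:
        new_state = fedavg(updates)

    client_sets = [u.prototypes for u in updates]
    if cfg.prototype_merge == "merge" and server_prototypes.prototypes:
        new_protos = aggregate_prototypes(client_sets + [server_prototypes])
    else:
        new_protos = aggregate_prototypes(client_sets)

    model = TinyCNN(global_state.num_classes, input_stats=input_stats)
    load_state_into_model(model, new_state)
    metrics = evaluate_model(
        model,
        test_set,
        label=cfg.privacy_mode.value,
        prototypes=new_protos if cfg.eval_with_prototypes else None,
    )
    per_client_MB = per_round_cost(
        total_params(cfg.arch, global_state.num_classes),
        cfg.skip_ratio,
        sa_enabled=cfg.privacy_mode.uses_sa,
        overhead_factor=cfg.sa.overhead_factor,
    )
    return RoundResult(round_index, new_state, new_protos, metrics, per_client_MB * cfg.n_clients)


def run_experiment(
    cfg: ExperimentConfig,
    train_set: LabeledDataset,
    test_set: LabeledDataset,
    out_dir: str | Path | None = None,
) -> tuple[list[RoundResult], MetricsRow]:
    """Run a full federated experiment from a fresh global model.

    The training set is partitioned across clients by Dirichlet sampling
    with the configured alpha; input standardization statistics are
    computed once from the training split and shared by every client and
    the evaluator. Returns all round results plus a final summary row
    (the last round's metrics with the experiment's wall-clock training
    time). With ``out_dir`` set, writes per-round metrics and a
    ``federated_learning_results.csv`` summary.
    """
    t0 = time.perf_counter()
    plan = dirichlet_partition(train_set, cfg.n_clients, cfg.alpha, seed=cfg.seed)
    shards = {k: train_set.subset(idx) for k, idx in plan.assignments.items()}
    px = train_set.pixel_array()
    input_stats = (float(px.mean()), float(px.std()) or 1.0)
    _, global_state = build_model(
        cfg.arch, train_set.n_classes, seed=cfg.seed, input_stats=input_stats
    )
    protos = PrototypeSet()
    results: list[RoundResult] = []
    for r in range(cfg.rounds):
        res = run_round(
            global_state, protos, cfg, shards, test_set, round_index=r, input_stats=input_stats
        )
        global_state, protos = res.global_state, res.global_prototypes
        results.append(res)
    summary = replace(results[-1].metrics)
    summary.training_time_s = time.perf_counter() - t0
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        per_round = pd.DataFrame(
            [
                {"round": r.round_index, "comm_MB": r.comm_MB, **r.metrics.as_dict()}
                for r in results
            ]
        )
        per_round.to_csv(out / f"rounds_{cfg.privacy_mode.value}.csv", index=False)
        rows_to_frame([summary]).assign(configuration=cfg.privacy_mode.value).to_csv(
            out / "federated_learning_results.csv", index=False
        )
    return results, summary


def run_configurations(
    base_cfg: ExperimentConfig,
    modes: list[PrivacyMode],
    train_set: LabeledDataset,
    test_set: LabeledDataset,
    out_dir: str | Path | None = None,
) -> pd.DataFrame:
    """Run several privacy configurations and collect one summary row each."""
    rows = []
    for mode in modes:
        cfg = replace(base_cfg, privacy_mode=PrivacyMode(mode))
        results, summary = run_experiment(cfg, train_set, test_set)
        rows.append(
            {
                "configuration": cfg.privacy_mode.value,
                **{k: v for k, v in summary.as_dict().items() if k != "label"},
                "total_comm_MB": sum(r.comm_MB for r in results),
            }
        )
    frame = pd.DataFrame(rows)
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        frame.to_csv(out / "federated_learning_results.csv", index=False)
    return frame
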