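"""Analytic communication-cost accounting.

Per federated round each client uploads its trainable parameters as
32-bit floats: cost_MB = total_params * (1 - skip_ratio) * 4 / 1024^2.
Secure aggregation multiplies the per-round cost by a fixed overhead
factor (default 1.15) covering masking and key-exchange traffic. Total
experiment cost is per-round cost x clients x rounds.

Note the continuous (1 - skip_ratio) formula is used for accounting even
though the trainable skip *plan* freezes whole groups and so realizes a
slightly different discrete count; the discrepancy is reported by
:func:`cost_report`.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = ["CostReport", "per_round_cost", "total_cost", "cost_report"]

BYTES_PER_PARAM = 4
MB = 1024.0 * 1024.0


@dataclass(frozen=True)
class CostReport:
    """Communication cost of one experiment configuration."""

    per_round_MB: float  # per client per round
    total_MB: float
    n_clients: int
    rounds: int
    skip_ratio: float
    sa_enabled: bool
    total_params: int
    trainable_params_continuous: float
    trainable_params_plan: int | None = None


def per_round_cost(
    total_params: int,
    skip_ratio: float,
    sa_enabled: bool = False,
    overhead_factor: float = 1.15,
) -> float:
    """Upload cost in MB for one client in one round."""
    if total_params <= 0:
        raise ValueError("total_params must be positive")
    if not 0.0 <= skip_ratio < 1.0:
        raise ValueError("skip_ratio must be in [0, 1)")
    if overhead_factor < 1.0:
        raise ValueError("overhead_factor must be >= 1")
    trainable = total_params * (1.0 - skip_ratio)
    mb = trainable * BYTES_PER_PARAM / MB
    if sa_enabled:
        mb *= overhead_factor
    return mb


def total_cost(per_round_MB: float, n_clients: int, rounds: int) -> float:
    """Whole-experiment cost: per-round per-client MB x clients x rounds."""
    if per_round_MB < 0 or n_clients <= 0 or rounds <= 0:
        raise ValueError("arguments must be positive")
    return per_round_MB * n_clients * rounds


def cost_report(
    total_params: int,
    skip_ratio: float,
    n_clients: int,
    rounds: int,
    sa_enabled: bool = False,
    overhead_factor: float = 1.15,
    trainable_params_plan: int | None = None,
) -> CostReport:
    per_round = per_round_cost(total_params, skip_ratio, sa_enabled, overhead_factor)
    return CostReport(
        per_round_MB=per_round,
        total_MB=total_cost(per_round, n_clients, rounds),
        n_clients=n_clients,
        rounds=rounds,
        skip_ratio=skip_ratio,
        sa_enabled=sa_enabled,
        total_params=total_params,
        trainable_params_continuous=total_params * (1.0 - skip_ratio),
        trainable_params_plan=trainable_params_plan,
    )
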