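"""Privacy mechanisms: differential privacy, simulated secure aggregation,
privacy accounting and leakage scoring.

Differential privacy follows the Gaussian mechanism: an update vector is
clipped to L2 norm C and perturbed with N(0, sigma^2 C^2 I) noise, so the
per-coordinate noise standard deviation is sigma * C. Secure aggregation
is simulated by Bonawitz-style pairwise additive masking: each unordered
client pair (i, j) shares a seed from which an antisymmetric mask pair
(+m_ij for i, -m_ij for j) is drawn, so individual masked vectors are
uninformative while the sum of all masked vectors equals the raw sum.

Leakage scores are *assigned relative rankings* per privacy configuration
(1.0 = no protection), not measured attack success rates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .client import PrototypeSet

__all__ = [
    "DPConfig",
    "SAConfig",
    "PrivacyMode",
    "clip_and_noise",
    "noise_prototypes",
    "secure_mask",
    "leakage_score",
    "leakage_from_budget",
    "gaussian_budget",
    "LEAKAGE_SCORES",
]


class PrivacyMode(str, Enum):
    NO_PRIVACY = "no_privacy"
    DP_ONLY = "dp_only"
    SA_ONLY = "sa_only"
    DP_SA = "dp_sa"

    @property
    def uses_dp(self) -> bool:
        return self in (PrivacyMode.DP_ONLY, PrivacyMode.DP_SA)

    @property
    def uses_sa(self) -> bool:
        return self in (PrivacyMode.SA_ONLY, PrivacyMode.DP_SA)


@dataclass(frozen=True)
class DPConfig:
    """Gaussian-mechanism parameters: clip norm C, noise multiplier sigma,
    breach probability delta, and the RNG seed for the noise draws."""

    clip_norm: float = 1.0
    noise_multiplier: float = 0.5
    delta: float = 1e-5
    seed: int = 42

    def __post_init__(self) -> None:
        if self.clip_norm <= 0:
            raise ValueError("clip_norm must be positive")
        if self.noise_multiplier < 0:
            raise ValueError("noise_multiplier must be non-negative")
        if not 0.0 < self.delta < 1.0:
            raise ValueError("delta must be in (0, 1)")


@dataclass(frozen=True)
class SAConfig:
    """Pairwise-masking parameters. ``overhead_factor`` is the multiplicative
    communication overhead of the masking/key exchange applied by the cost
    model when secure aggregation is on."""

    base_seed: int = 42
    mask_scale: float = 1.0
    overhead_factor: float = 1.15

    def __post_init__(self) -> None:
        if self.mask_scale <= 0:
            raise ValueError("mask_scale must be positive")
        if self.overhead_factor < 1.0:
            raise ValueError("overhead_factor must be >= 1")

    def pair_rng(self, i: int, j: int) -> np.random.Generator:
        """Shared generator for the unordered client pair {i, j}."""
        lo, hi = (i, j) if i < j else (j, i)
        return np.random.default_rng([self.base_seed, lo, hi])


def clip_and_noise(
    update: np.ndarray, dp: DPConfig, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Clip an update to L2 norm C and add N(0, sigma^2 C^2) noise per
    coordinate. With sigma = 0 this is pure norm clipping."""
    g = np.asarray(update, dtype=np.float64)
    if not np.all(np.isfinite(g)):
        raise ValueError("update contains non-finite values")
    norm = float(np.linalg.norm(g))
    clipped = g / max(1.0, norm / dp.clip_norm)
    if dp.noise_multiplier == 0.0:
        return clipped
    if rng is None:
        rng = np.random.default_rng(dp.seed)
    noise_sd = dp.noise_multiplier * dp.clip_norm
    return clipped + rng.normal(0.0, noise_sd, size=clipped.shape)


def noise_prototypes(
    protos: PrototypeSet, dp: DPConfig, rng: np.random.Generator | None = None
) -> PrototypeSet:
    """Clip-and-noise every class prototype vector; support counts are
    left untouched."""
    if rng is None:
        rng = np.random.default_rng(dp.seed)
    out = {c: clip_and_noise(v, dp, rng) for c, v in protos.prototypes.items()}
    return PrototypeSet(out, dict(protos.counts))


def secure_mask(
    updates: dict[int, np.ndarray], sa: SAConfig
) -> dict[int, np.ndarray]:
    """Apply pairwise antisymmetric masks to a set of client vectors.

    Client i's vector gains +m_ij for every peer j > i and -m_ji for every
    j < i, with m drawn from the pair's shared seed; the masks cancel
    exactly in the sum over clients.
    """
    ids = sorted(updates)
    if len(ids) < 2:
        raise ValueError("secure aggregation needs at least 2 clients")
    lengths = {updates[i].size for i in ids}
    if len(lengths) != 1:
        raise ValueError("all client vectors must have equal length")
    (length,) = lengths
    masked = {i: np.asarray(updates[i], dtype=np.float64).copy() for i in ids}
    for a in range(len(ids)):
        for b in range(a + 1, len(ids)):
            i, j = ids[a], ids[b]
            m = sa.pair_rng(i, j).normal(0.0, sa.mask_scale, size=length)
            masked[i] += m
            masked[j] -= m
    return masked


#: Assigned leakage scores per privacy configuration (relative ranking only).
LEAKAGE_SCORES: dict[PrivacyMode, float] = {
    PrivacyMode.NO_PRIVACY: 1.0,
    PrivacyMode.DP_ONLY: 0.4,
    PrivacyMode.SA_ONLY: 0.6,
    PrivacyMode.DP_SA: 0.2,
}


def leakage_score(mode: PrivacyMode | str) -> float:
    """Relative privacy-leakage score of a configuration (1.0 = none)."""
    return LEAKAGE_SCORES[PrivacyMode(mode)]


def leakage_from_budget(epsilon: float) -> float:
    """Surrogate leakage used by the multi-objective search: 1 / epsilon."""
    if epsilon <= 0:
        raise ValueError("privacy budget epsilon must be positive")
    return 1.0 / epsilon


def gaussian_budget(sigma: float, delta: float, rounds: int = 1) -> float:
    """Conservative (epsilon, delta) accounting for the Gaussian mechanism.

    Per release, epsilon_0 = sqrt(2 ln(1.25/delta)) / sigma (the classical
    bound for sensitivity C with noise sd sigma*C); composed over rounds by
    basic composition. This is a deliberately loose stand-in for a moments
    accountant and overstates the true budget.
    """
    if sigma <= 0:
        raise ValueError("sigma must be positive")
    if not 0.0 < delta < 1.0:
        raise ValueError("delta must be in (0, 1)")
    if rounds < 1:
        raise ValueError("rounds must be >= 1")
    eps0 = math.sqrt(2.0 * math.log(1.25 / delta)) / sigma
    return rounds * eps0
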