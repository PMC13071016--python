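"""Multi-objective trade-off analysis: surrogate objectives, Pareto
filtering and NSGA-II.

The decision variables are the layer-skip ratio and the privacy budget
epsilon. Three objectives, all minimized:

* f1 — negated accuracy surrogate, base_acc - penalty_coef * skip_ratio
  (a cheap stand-in for retraining at every candidate; the linear penalty
  is calibrated so that 60% skipping costs about 2 accuracy points);
* f2 — per-round communication cost in MB at the candidate's skip ratio;
* f3 — privacy leakage surrogate 1 / epsilon.

NSGA-II is implemented in full: fast non-dominated sorting, crowding
distance, binary tournament on (rank, crowding), simulated binary
crossover, polynomial mutation, and elitist environmental selection.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .costs import per_round_cost
from .privacy import leakage_from_budget

__all__ = [
    "ConfigPoint",
    "surrogate_objectives",
    "pareto_filter",
    "fast_non_dominated_sort",
    "crowding_distance",
    "nsga2",
    "NSGA2Result",
    "hypervolume_2d",
]

#: default linear accuracy-penalty coefficient: penalty(0.6) = 0.02
DEFAULT_PENALTY_COEF = 0.02 / 0.6


@dataclass(frozen=True)
class ConfigPoint:
    """A candidate configuration (skip ratio, privacy budget epsilon)."""

    layer_skip_ratio: float
    privacy_budget: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.layer_skip_ratio < 1.0:
            raise ValueError("layer_skip_ratio must be in [0, 1)")
        if self.privacy_budget <= 0:
            raise ValueError("privacy_budget must be positive")


def surrogate_objectives(
    point: ConfigPoint,
    base_acc: float,
    total_params: int,
    penalty_coef: float = DEFAULT_PENALTY_COEF,
    penalty: str = "linear",
) -> np.ndarray:
    """Objective vector (negated accuracy surrogate, comm MB, leakage)."""
    if not 0.0 <= base_acc <= 1.0:
        raise ValueError("base_acc must be in [0, 1]")
    s = point.layer_skip_ratio
    drop = penalty_coef * (s * s if penalty == "quadratic" else s)
    acc = base_acc - drop
    cost = per_round_cost(total_params, s, sa_enabled=False, overhead_factor=1.0)
    return np.array([-acc, cost, leakage_from_budget(point.privacy_budget)])


def _dominates(a: np.ndarray, b: np.ndarray) -> bool:
    return bool(np.all(a <= b) and np.any(a < b))


def pareto_filter(points: Sequence[np.ndarray] | np.ndarray) -> list[int]:
    """Indices of the non-dominated points (all objectives minimized)."""
    f = np.asarray(points, dtype=np.float64)
    if f.ndim != 2 or f.shape[0] == 0:
        raise ValueError("need a non-empty 2-D objective array")
    n = f.shape[0]
    keep = []
    for i in range(n):
        dominated = False
        for j in range(n):
            if j != i and _dominates(f[j], f[i]):
                dominated = True
                break
        if not dominated:
            keep.append(i)
    return keep


def fast_non_dominated_sort(f: np.ndarray) -> list[list[int]]:
    """Partition points into non-domination ranks (rank 0 = Pareto front)."""
    n = f.shape[0]
    dominated_by: list[list[int]] = [[] for _ in range(n)]
    dom_count = np.zeros(n, dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            if _dominates(f[i], f[j]):
                dominated_by[i].append(j)
                dom_count[j] += 1
            elif _dominates(f[j], f[i]):
                dominated_by[j].append(i)
                dom_count[i] += 1
    fronts = [[i for i in range(n) if dom_count[i] == 0]]
    while fronts[-1]:
        nxt = []
        for i in fronts[-1]:
            for j in dominated_by[i]:
                dom_count[j] -= 1
                if dom_count[j] == 0:
                    nxt.append(j)
        fronts.append(nxt)
    return fronts[:-1]


def crowding_distance(f: np.ndarray) -> np.ndarray:
    """Crowding distances of a set of objective vectors; boundary points
    (per objective) get infinity."""
    n, m = f.shape
    d = np.zeros(n)
    if n <= 2:
        return np.full(n, np.inf)
    for k in range(m):
        order = np.argsort(f[:, k], kind="stable")
        fk = f[order, k]
        d[order[0]] = d[order[-1]] = np.inf
        span = fk[-1] - fk[0]
        if span <= 0:
            continue
        d[order[1:-1]] += (fk[2:] - fk[:-2]) / span
    return d


@dataclass
class NSGA2Result:
    x: np.ndarray        # final population decision variables (pop, n_var)
    f: np.ndarray        # final population objectives (pop, n_obj)
    front_indices: list[int]   # rank-0 members of the final population
    front_history: list[np.ndarray]  # rank-0 objective sets per generation

    @property
    def front_x(self) -> np.ndarray:
        return self.x[self.front_indices]

    @property
    def front_f(self) -> np.ndarray:
        return self.f[self.front_indices]


def _sbx(p1, p2, lo, hi, eta, rng):
    u = rng.random(p1.shape)
    beta = np.where(
        u <= 0.5, (2 * u) ** (1 / (eta + 1)), (1 / (2 * (1 - u))) ** (1 / (eta + 1))
    )
    c1 = 0.5 * ((1 + beta) * p1 + (1 - beta) * p2)
    c2 = 0.5 * ((1 - beta) * p1 + (1 + beta) * p2)
    return np.clip(c1, lo, hi), np.clip(c2, lo, hi)


def _poly_mutation(x, lo, hi, eta, pm, rng):
    y = x.copy()
    for k in range(x.size):
        if rng.random() < pm:
            u = rng.random()
            span = hi[k] - lo[k]
            if u < 0.5:
                delta = (2 * u) ** (1 / (eta + 1)) - 1
            else:
                delta = 1 - (2 * (1 - u)) ** (1 / (eta + 1))
            y[k] = np.clip(y[k] + delta * span, lo[k], hi[k])
    return y


def nsga2(
    objective_fn: Callable[[np.ndarray], np.ndarray],
    bounds: Sequence[tuple[float, float]],
    pop_size: int = 40,
    generations: int = 60,
    seed: int = 42,
    eta_crossover: float = 15.0,
    eta_mutation: float = 20.0,
    p_mutation: float | None = None,
) -> NSGA2Result:
    """Elitist NSGA-II over box-bounded real decision variables.

    ``objective_fn`` maps one decision vector to an objective vector (all
    objectives minimized). Deterministic under ``seed``.
    """
    lo = np.array([b[0] for b in bounds], dtype=np.float64)
    hi = np.array([b[1] for b in bounds], dtype=np.float64)
    if np.any(hi <= lo):
        raise ValueError("each bound must satisfy low < high")
    if pop_size < 4 or pop_size % 2:
        raise ValueError("pop_size must be even and >= 4")
    if generations < 1:
        raise ValueError("generations must be >= 1")
    n_var = lo.size
    pm = p_mutation if p_mutation is not None else 1.0 / n_var
    rng = np.random.default_rng(seed)

    x = lo + rng.random((pop_size, n_var)) * (hi - lo)
    f = np.array([objective_fn(xi) for xi in x])
    history: list[np.ndarray] = []

    def rank_and_crowd(fm):
        fronts = fast_non_dominated_sort(fm)
        rank = np.empty(fm.shape[0], dtype=int)
        crowd = np.empty(fm.shape[0])
        for r, members in enumerate(fronts):
            rank[members] = r
            crowd[members] = crowding_distance(fm[members])
        return fronts, rank, crowd

    fronts, rank, crowd = rank_and_crowd(f)
    history.append(f[fronts[0]].copy())

    for _ in range(generations):
        # binary tournament on (rank, crowding)
        def pick():
            i, j = rng.integers(0, pop_size, size=2)
            if rank[i] < rank[j] or (rank[i] == rank[j] and crowd[i] > crowd[j]):
                return i
            return j

        children = []
        while len(children) < pop_size:
            p1, p2 = x[pick()], x[pick()]
            if rng.random() < 0.9:
                c1, c2 = _sbx(p1, p2, lo, hi, eta_crossover, rng)
            else:
                c1, c2 = p1.copy(), p2.copy()
            children.append(_poly_mutation(c1, lo, hi, eta_mutation, pm, rng))
            children.append(_poly_mutation(c2, lo, hi, eta_mutation, pm, rng))
        cx = np.array(children[:pop_size])
        cf = np.array([objective_fn(xi) for xi in cx])

        # elitist environmental selection on parents + children
        ax = np.vstack([x, cx])
        af = np.vstack([f, cf])
        afronts = fast_non_dominated_sort(af)
        chosen: list[int] = []
        for members in afronts:
            if len(chosen) + len(members) <= pop_size:
                chosen.extend(members)
            else:
                cd = crowding_distance(af[members])
                order = np.argsort(-cd, kind="stable")
                chosen.extend(np.array(members)[order[: pop_size - len(chosen)]].tolist())
                break
        x, f = ax[chosen], af[chosen]
        fronts, rank, crowd = rank_and_crowd(f)
        history.append(f[fronts[0]].copy())

    return NSGA2Result(x=x, f=f, front_indices=fronts[0], front_history=history)


def hypervolume_2d(front: np.ndarray, ref: tuple[float, float]) -> float:
    """Dominated hypervolume of a 2-D minimization front w.r.t. a reference
    point (points beyond the reference contribute nothing)."""
    pts = np.asarray(front, dtype=np.float64)
    pts = pts[(pts[:, 0] < ref[0]) & (pts[:, 1] < ref[1])]
    if pts.size == 0:
        return 0.0
    pts = pts[np.argsort(pts[:, 0], kind="stable")]
    hv = 0.0
    prev_y = ref[1]
    for xx, yy in pts:
        if yy < prev_y:
            hv += (ref[0] - xx) * (prev_y - yy)
            prev_y = yy
    return hv
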