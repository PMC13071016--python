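"""Multi-objective trade-off search with NSGA-II.

Optimizes (layer-skip ratio, privacy budget epsilon) against three
surrogate objectives — negated accuracy, per-round communication MB, and
leakage 1/epsilon — for a ResNet50-sized model, then prints the Pareto
front. Every front row is a non-dominated compromise: moving along the
front trades accuracy against bandwidth at the largest feasible epsilon.
"""

import numpy as np

import protofed as pf
from protofed.pareto import ConfigPoint

params = pf.total_params("resnet50", num_classes=4)

def objectives(x: np.ndarray) -> np.ndarray:
    return pf.surrogate_objectives(ConfigPoint(float(x[0]), float(x[1])), base_acc=0.96, total_params=params)

res = pf.nsga2(objectives, bounds=[(0.0, 0.9), (0.5, 10.0)], pop_size=40, generations=60, seed=42)
front = sorted(
    zip(res.front_x[:, 0], res.front_x[:, 1], res.front_f[:, 0], res.front_f[:, 1], res.front_f[:, 2]),
    key=lambda r: r[3],
)
print(f"{'skip':>6s} {'eps':>6s} {'acc_surrogate':>14s} {'cost_MB':>9s} {'leakage':>8s}")
for s, e, f1, f2, f3 in front[:: max(1, len(front) // 12)]:
    print(f"{s:6.3f} {e:6.2f} {-f1:14.4f} {f2:9.2f} {f3:8.3f}")
print(f"({len(front)} non-dominated configurations)")
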