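# protofed

A desk-scale simulator of **privacy-aware federated learning** for
multi-class medical-style image classification.

Hospitals cannot pool MRI scans: privacy regulation forbids sharing raw
patient data, so collaborative models must be trained federated — each
site trains locally and shares only model updates. That introduces three
coupled problems: statistical heterogeneity (different sites see different
case mixes), communication cost (modern backbones upload tens of MB per
round), and privacy leakage (updates can still be inverted). `protofed`
simulates this whole setting in-process on one CPU, for researchers who
want to study the interactions between the mitigation mechanisms rather
than train production models:

* **non-IID data** — class-wise Dirichlet(α) partitioning of an image
  dataset across K simulated clients;
* **layer skipping** — freezing early parameter groups so only a fraction
  of the network is trained and transmitted;
* **FedAvg** — sample-count-weighted aggregation
  ω_{t+1} = Σ_k (n_k/n) ω_{t+1}^k;
* **prototype aggregation** — count-weighted class centroids in feature
  space, P(c) = Σ_k n_k(c) p_k(c) / Σ_k n_k(c);
* **differential privacy** — clip each update to L2 norm C and add
  Gaussian noise N(0, σ²C²I);
* **secure aggregation** — Bonawitz-style pairwise antisymmetric masking,
  so the server sees only the sum of client updates;
* **communication accounting** — cost_MB = params × (1 − skip_ratio) ×
  4 / 1024², with a 1.15× overhead when secure aggregation is on;
* **multi-objective trade-offs** — NSGA-II over (skip ratio, privacy
  budget ε) minimizing (−accuracy, communication MB, leakage 1/ε).

The trainable backbone is a small deterministic NumPy CNN; large
backbones (ResNet50, EfficientNet-B0, ConvNeXt-T, Swin-T) are registered
with exact analytic per-stage parameter inventories that drive skip
planning and cost analysis. A built-in generator produces 4-class
synthetic images (distinct lesion motifs on a brain-like disk) standing
in for folder-per-class MRI datasets; real image folders load through the
same interface.

## Worked example

```python
import protofed as pf

ds = pf.generate_synthetic_dataset(200, 4, (32, 32), 0.05, seed=42)
train, test = pf.stratified_split(ds, 0.8, seed=42)
cfg = pf.ExperimentConfig(
    privacy_mode=pf.PrivacyMode.NO_PRIVACY,
    training=pf.TrainingConfig.desk_scale(seed=42),
    seed=42,
)
results, summary = pf.run_experiment(cfg, train, test)
print([round(r.metrics.accuracy, 3) for r in results])
print(round(summary.accuracy, 4), round(summary.f1, 4))
```

prints (5 clients, Dirichlet α = 0.5, 8 rounds, 5 local epochs):

```
[0.25, 0.525, 0.75, 0.863, 0.75, 1.0, 0.831, 1.0]
1.0 1.0
```

— the global model's held-out accuracy per round, oscillating early while
the heterogeneous clients disagree, then converging; the final summary row
is what `federated_learning_results.csv` stores. Running the same
experiment with `privacy_mode="dp_sa"` collapses accuracy to chance
(≈0.25): a noise multiplier of 0.5 on a norm-1-clipped parameter delta
drowns the update, the accuracy half of the privacy–utility trade-off.
The analytic side (`examples/02_skip_plans_and_costs.py`):

```
SA=False: 53.82 MB/client/round, 2152.97 MB total
SA=True:  61.90 MB/client/round, 2475.92 MB total
```

for ResNet50 with a 4-way head (23,516,228 parameters) at skip ratio 0.4,
5 clients, 8 rounds.

Each script in `examples/` demonstrates one capability (data and
partitioning, skip plans and costs, privacy mechanisms, a full federated
experiment, Pareto optimization) and prints what the numbers mean. A thin
CLI wraps the same functions: `protofed generate-data`, `partition`,
`inspect-model`, `train-federated`, `analyze-costs`, `optimize`.

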