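# Methods

## What the simulator models

`protofed` reproduces, in one process, the workflow of a multi-hospital
federated imaging study: a global classifier is broadcast to K clients,
each client trains it on its private shard for a few epochs, the returned
updates pass through optional privacy mechanisms, and the server
aggregates them into the next global model while tracking test metrics,
communication volume and privacy exposure. All randomness flows from
explicit integer seeds; repeated runs with the same configuration are
bit-identical.

### Federated aggregation

FedAvg weights each client's full post-training parameter state by its
sample share: ω_{t+1} = Σ_k (n_k/n) ω_{t+1}^k. Full states, not deltas,
are exchanged; batch-normalization-style buffers do not arise because the
desk-scale backbone is norm-free.

Class prototypes — the mean penultimate (globally pooled) feature vector
of each class a client holds — are aggregated count-weighted per class:
P(c) = Σ_k n_k(c) p_k(c) / Σ_k n_k(c). The server carries prototypes
across rounds and merges its accumulated set with each round's client
sets by the same rule (`prototype_merge="merge"`; `"replace"` keeps only
the current round). By default the aggregated prototypes do **not** feed
back into the classifier; two optional couplings exist because the
question is genuinely open in prototype-based FL designs: a
nearest-centroid evaluator (`eval_with_prototypes=True`) and a local
prototype-alignment penalty pulling client features toward the broadcast
centroids (`TrainingConfig.align_weight`, default 0).

### Local training

Each client minimizes mean cross-entropy plus an L2 weight penalty,
realized as Adam weight decay (coupled decay, coefficient 1e-4). The
reference protocol is Adam, batch 64, 5 local epochs per round. Two
learning-rate presets exist:

* `TrainingConfig()` — lr 1e-3, the fine-tuning regime appropriate to
  large pretrained backbones;
* `TrainingConfig.desk_scale()` — lr 1e-2, calibrated for the scratch
  NumPy CNN, which trains from random initialization for only tens of
  optimizer steps per round and needs the larger step size. All synthetic
  studies in the tests and examples use this preset.

Data-loader shuffling is seeded per (client, round), so client order and
round count never perturb each other's streams.

### Layer skipping

A skip plan freezes whole parameter groups earliest-first (the
transfer-learning convention: early layers are generic) until the frozen
fraction reaches `skip_ratio × total_params`; the classifier head is
never frozen, so `skip_ratio = 1` is rejected. Frozen groups provably
receive no optimizer update and return bit-identical.

Communication cost deliberately uses the *continuous* accounting
`params × (1 − skip_ratio) × 4 bytes`, not the discrete greedy plan's
trainable count: the analytic cost tables are defined on the continuous
formula, and for coarse-grained inventories the greedy count can differ
substantially (e.g. ResNet50 at ratio 0.4 freezes through stage4, leaving
only the 8,196-parameter head trainable). Both numbers are reported by
`cost_report` and the `inspect-model` command.

### The backbone registry

`tiny_cnn` is the only trainable architecture: three 3×3 convolution
blocks (8/16/32 channels) with ReLU and 2×2 max pooling, global average
pooling and a linear head; float64 NumPy throughout, im2col convolutions,
hand-written backward pass, 6,020 parameters at 4 classes. Float64 makes
the secure-aggregation transparency property hold to ~1e-13 and training
exactly reproducible.

ResNet50, EfficientNet-B0, ConvNeXt-Tiny and Swin-Tiny are registered as
analytic per-stage parameter inventories computed from the published
topologies (verified against the known ImageNet totals: 25,557,032 /
5,288,548 / 28,589,128 / 28,288,354 with 1000-way heads). They support
skip planning and cost analysis; instantiating them as trainable models
is out of scope for a CPU-only simulator and raises a clear error.

### Differential privacy

The Gaussian mechanism: an update vector is clipped to L2 norm C
(default 1.0) and perturbed with N(0, σ²C²I) (noise multiplier σ,
default 0.5). In DP modes the mechanism is applied to each client's
parameter *delta* (post-training state minus broadcast state) and to each
class prototype; support counts are never noised. Privacy accounting uses
the classical single-release bound ε₀ = √(2 ln(1.25/δ))/σ composed
linearly over rounds — deliberately conservative, and labelled as such; a
moments-accountant would give a far tighter ε. δ defaults to 1e-5, an
artifact choice (the reference protocol leaves ε and δ unspecified).

With σ = 0.5 and C = 1 the per-coordinate noise sd (0.5) exceeds the
magnitude of a norm-1-clipped delta spread over thousands of
coordinates, so DP configurations collapse to chance accuracy on the
desk-scale model. This is the honest behaviour of the mechanism at these
settings, and the simulator reports it rather than hiding it; the
qualitative privacy-utility ordering (no_privacy ≥ sa_only ≥ DP modes)
is the reproducible finding.

### Secure aggregation

Simulated Bonawitz-style pairwise masking, without cryptography: each
unordered client pair {i, j} shares a seed from which a mask m_ij is
drawn; client i adds it, client j subtracts it, so the sum over clients
is unchanged while each individual vector is offset by a sum of masks
unknown to the server. To commute with weighted FedAvg, clients pre-scale
their flattened states by n_k/n before masking; the server sums the
masked vectors. The functional contract — server learns only the sum —
holds exactly; the threat model is honest-but-curious, and no claim is
made about malicious or colluding parties. Secure aggregation multiplies
communication cost by a fixed overhead factor (default 1.15) covering
mask/key exchange.

### Leakage scores

Per configuration: no_privacy 1.0, dp_only 0.4, sa_only 0.6, dp_sa 0.2.
These are *assigned relative rankings*, not measured attack success
rates — no gradient-inversion or prototype-reconstruction attack is
implemented — and they should be read only as an ordering.

### Multi-objective optimization

NSGA-II (fast non-dominated sort, crowding distance, binary tournament,
SBX η=15, polynomial mutation η=20, p_m = 1/n_var, crossover rate 0.9,
population 40, 60 generations — all configurable) searches
(skip_ratio ∈ [0,1), ε > 0) against three cheap surrogates: negated
accuracy `base_acc − penalty_coef × skip_ratio` (linear penalty
calibrated so 60% skipping costs 0.02 accuracy; a quadratic option
exists), per-round communication MB from the cost model, and leakage
1/ε. Surrogates, not retraining, score each candidate; a hook allows
substituting measured accuracies on small grids. A brute-force O(n²)
Pareto filter serves as the correctness oracle for the rank-0 front.

## The synthetic data generator

Each class is a deterministic structural motif on a dark elliptical
"brain" disk with radial shading and faint sinusoidal folds: class 0 has
no lesion; class 1 a solid bright disk (radius 0.14–0.17 of image side);
class 2 a thin bright bar (0.04 × 0.30) at random orientation; class 3 a
large bright ring (outer radius 0.26–0.30) with dark core. Pose, size and
orientation are jittered per sample; additive Gaussian pixel noise
(sd 0.05 by default) is clipped back to [0,1]. The motifs were
deliberately given distinct shapes *and* distinct total bright areas so
they remain separable after aggressive spatial pooling — an earlier
design with near-equal lesion areas caused the federated model to merge
two classes.

What the generator does **not** emulate: scanner/protocol domain shifts,
intensity non-uniformity, anatomy, 3-D structure, label noise, class
imbalance. Passing tests therefore demonstrate the correctness and
interaction of the federated mechanisms, not clinical performance;
absolute accuracies on this data say nothing about real MRI.

Augmentation (rotation ±15°, horizontal flip, zoom ±10%) is implemented
for training time but off by default: the generator already draws
i.i.d. pose variation, so augmentation is a real-data concern here.
Images are normalized to [0,1] at load time; experiments standardize
inputs with the training split's global mean/sd, shared by all clients
and the evaluator.

## Problem sizes and numerical choices

* Desk-scale study: 4 classes × 200 images at 32×32, 80/20 stratified
  split, 5 clients, Dirichlet α = 0.5, 8 rounds, 5 local epochs — one
  configuration runs in ~25 s on one CPU. The separability check uses
  64×64 images; both sizes use the same motifs.
* Dirichlet partitioning draws a client-proportion vector per class and
  apportions indices by largest-remainder rounding (conserves totals
  exactly); draws are repeated (≤100) until every client has
  ≥ `min_per_client` (default 1) samples.
* Stratified splitting takes `round(train_frac × class_count)` per class,
  clamped so neither side is empty; classes with fewer than 2 samples are
  rejected.
* All parameter vectors are float64; aggregation tolerances in tests are
  1e-6–1e-7 relative, far above accumulated rounding (~1e-13).
* Ties in best-F1 model selection break toward first occurrence.
* Precision/recall/F1/ROC-AUC are support-weighted (one-vs-rest for
  AUC); weighted recall equals accuracy by construction, a useful
  consistency check on reported tables. Training time is recorded but
  hardware-dependent, so no test asserts it.

## Known limitations

* No client dropout, stragglers, partial participation or asynchrony;
  every client trains every round.
* Secure aggregation is a functional simulation, not a cryptographic
  protocol.
* The ε accounting is deliberately loose (basic composition of the
  classical Gaussian bound).
* Leakage scores are assigned constants, not measured attack outcomes.
* Large backbones are inventory-only; reported desk-scale accuracies come
  from the scratch NumPy CNN on synthetic motifs.
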