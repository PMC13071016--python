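"""Generate a synthetic 4-class image dataset and partition it across
simulated hospitals with Dirichlet label skew.

Prints the train/test class counts and each client's per-class sample
counts: with alpha = 0.5 the shards are strongly non-IID (each client is
dominated by one or two classes), which is the statistical heterogeneity
the federated simulation studies.
"""

import protofed as pf

ds = pf.generate_synthetic_dataset(n_per_class=200, n_classes=4, image_size=(32, 32), noise_sd=0.05, seed=42)
train, test = pf.stratified_split(ds, train_frac=0.8, seed=42)
print(f"dataset: {len(ds)} images, classes {ds.class_names}")
print(f"train per-class counts: {train.class_counts().tolist()}")
print(f"test  per-class counts: {test.class_counts().tolist()}")

plan = pf.dirichlet_partition(train, n_clients=5, alpha=0.5, seed=42)
print("\nDirichlet(0.5) partition (rows = clients, columns = classes):")
for k in sorted(plan.assignments):
    print(f"  client {k}: n={len(plan.assignments[k]):3d}  per-class={plan.class_counts[k].tolist()}")
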