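import numpy as np
import pytest

import protofed as pf
from protofed.data import ImageSample, LabeledDataset


@pytest.fixture(scope="session")
def small_dataset() -> LabeledDataset:
    """40-sample synthetic dataset (10 per class) at 32x32."""
    return pf.generate_synthetic_dataset(10, 4, (32, 32), 0.05, seed=42)


@pytest.fixture(scope="session")
def medium_dataset() -> LabeledDataset:
    """200-per-class synthetic dataset at 32x32, the desk-scale study size."""
    return pf.generate_synthetic_dataset(200, 4, (32, 32), 0.05, seed=42)


def make_separable_shard(n_per_class: int = 25, seed: int = 0) -> LabeledDataset:
    """A trivially (linearly) separable shard: each class is a constant
    brightness level plus light pixel noise."""
    rng = np.random.default_rng(seed)
    samples = []
    for c in range(4):
        for _ in range(n_per_class):
            img = np.clip(
                np.full((32, 32), 0.15 + 0.22 * c) + rng.normal(0, 0.03, (32, 32)), 0, 1
            )
            samples.append(ImageSample(img, c))
    return LabeledDataset(samples, ["c0", "c1", "c2", "c3"], (32, 32))


@pytest.fixture(scope="session")
def separable_shard() -> LabeledDataset:
    return make_separable_shard()
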