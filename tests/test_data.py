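"""Synthetic generator, splitting, Dirichlet partitioning and folder I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import protofed as pf
from protofed.data import augment_batch


class TestGenerator:
    def test_counts_and_bounds(self, small_dataset):
        assert len(small_dataset) == 40
        assert np.array_equal(small_dataset.class_counts(), [10, 10, 10, 10])
        px = small_dataset.pixel_array()
        assert px.shape == (40, 1, 32, 32)
        assert px.min() >= 0.0 and px.max() <= 1.0

    @pytest.mark.parametrize("noise_sd", [0.0, 0.05])
    def test_determinism(self, noise_sd):
        a = pf.generate_synthetic_dataset(5, 4, (32, 32), noise_sd, seed=7)
        b = pf.generate_synthetic_dataset(5, 4, (32, 32), noise_sd, seed=7)
        assert np.array_equal(a.pixel_array(), b.pixel_array())
        assert np.array_equal(a.labels, b.labels)

    def test_classes_have_distinct_motifs(self):
        ds = pf.generate_synthetic_dataset(20, 4, (32, 32), 0.0, seed=1)
        px = ds.pixel_array()[:, 0]
        means = [px[ds.labels == c].mean() for c in range(4)]
        # lesion classes add bright area over the lesion-free background
        assert all(m > means[0] for m in means[1:])

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(n_per_class=0),
            dict(n_per_class=-3),
            dict(n_classes=1),
            dict(image_size=(8, 8)),
            dict(noise_sd=-0.1),
        ],
    )
    def test_invalid_arguments(self, kwargs):
        base = dict(n_per_class=5, n_classes=4, image_size=(32, 32), noise_sd=0.05, seed=0)
        base.update(kwargs)
        with pytest.raises(ValueError):
            pf.generate_synthetic_dataset(**base)


class TestStratifiedSplit:
    @pytest.mark.parametrize(
        "frac,per_class_train,per_class_test", [(0.8, 8, 2), (0.5, 5, 5)]
    )
    def test_per_class_counts(self, small_dataset, frac, per_class_train, per_class_test):
        tr, te = pf.stratified_split(small_dataset, frac, seed=3)
        assert np.array_equal(tr.class_counts(), [per_class_train] * 4)
        assert np.array_equal(te.class_counts(), [per_class_test] * 4)

    def test_disjoint_and_deterministic(self, small_dataset):
        tr1, te1 = pf.stratified_split(small_dataset, 0.8, seed=5)
        tr2, te2 = pf.stratified_split(small_dataset, 0.8, seed=5)
        ids1 = {s.source_id for s in tr1.samples}
        assert ids1.isdisjoint({s.source_id for s in te1.samples})
        assert ids1 == {s.source_id for s in tr2.samples}

    def test_errors(self, small_dataset):
        with pytest.raises(ValueError):
            pf.stratified_split(small_dataset, 1.0, seed=0)
        tiny = small_dataset.subset([0])  # one class with a single sample
        with pytest.raises(ValueError):
            pf.stratified_split(tiny, 0.8, seed=0)


class TestDirichletPartition:
    @settings(max_examples=20, deadline=None)
    @given(
        n_clients=st.integers(2, 6),
        alpha=st.floats(0.1, 50.0),
        seed=st.integers(0, 10_000),
    )
    def test_conservation(self, small_dataset, n_clients, alpha, seed):
        plan = pf.dirichlet_partition(small_dataset, n_clients, alpha, seed=seed)
        all_idx = sorted(i for v in plan.assignments.values() for i in v)
        assert all_idx == list(range(len(small_dataset)))
        labels = small_dataset.labels
        for k, idx in plan.assignments.items():
            assert np.array_equal(
                plan.class_counts[k], np.bincount(labels[idx], minlength=4)
            )

    def test_near_iid_at_huge_alpha(self):
        ds = pf.generate_synthetic_dataset(500, 4, (32, 32), 0.05, seed=0)
        global_props = ds.class_counts() / len(ds)
        for seed in range(10):
            plan = pf.dirichlet_partition(ds, 5, 1e6, seed=seed)
            for k, idx in plan.assignments.items():
                props = plan.class_counts[k] / len(idx)
                assert np.max(np.abs(props - global_props)) < 0.05

    def test_heterogeneity_decreases_with_alpha(self, medium_dataset):
        def spread(alpha):
            out = []
            for seed in range(10):
                plan = pf.dirichlet_partition(medium_dataset, 5, alpha, seed=seed)
                props = np.stack(
                    [
                        plan.class_counts[k] / max(len(plan.assignments[k]), 1)
                        for k in plan.assignments
                    ]
                )
                out.append(props.var(axis=0).mean())
            return np.mean(out)

        assert spread(0.1) > spread(100.0)

    def test_single_client_gets_everything(self, small_dataset):
        plan = pf.dirichlet_partition(small_dataset, 1, 0.5, seed=0)
        assert sorted(plan.assignments[0]) == list(range(len(small_dataset)))

    def test_min_per_client_infeasible(self, small_dataset):
        with pytest.raises(ValueError):
            pf.dirichlet_partition(small_dataset, 5, 0.5, seed=0, min_per_client=100)


class TestImageFolderIO:
    def test_roundtrip_preserves_labels(self, small_dataset, tmp_path):
        root = pf.write_image_folder(small_dataset, tmp_path / "ds")
        assert (root / "manifest.csv").exists()
        back = pf.read_image_folder(root, image_size=(32, 32))
        assert len(back) == len(small_dataset)
        assert back.class_names == sorted(small_dataset.class_names)
        # same label multiset after accounting for lexicographic reordering
        orig = sorted(small_dataset.class_names[s.label] for s in small_dataset.samples)
        new = sorted(back.class_names[s.label] for s in back.samples)
        assert orig == new

    def test_no_subdirectories_error(self, tmp_path):
        (tmp_path / "flat").mkdir()
        with pytest.raises(ValueError):
            pf.read_image_folder(tmp_path / "flat")

    def test_empty_class_dir_skipped_with_warning(self, small_dataset, tmp_path):
        root = pf.write_image_folder(small_dataset, tmp_path / "ds")
        (root / "zz_empty").mkdir()
        with pytest.warns(UserWarning, match="empty"):
            back = pf.read_image_folder(root, image_size=(32, 32))
        assert "zz_empty" not in back.class_names


def test_augment_preserves_shape_and_range(small_dataset):
    x = small_dataset.pixel_array()[:8]
    out = augment_batch(x, np.random.default_rng(0))
    assert out.shape == x.shape
    assert out.min() >= 0.0 and out.max() <= 1.0
    assert not np.array_equal(out, x)
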