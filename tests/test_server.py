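"""FedAvg, prototype aggregation and round orchestration."""

from dataclasses import replace

import numpy as np
import pytest

import protofed as pf
from protofed.client import ClientUpdate, PrototypeSet
from protofed.models import ModelState
from protofed.privacy import PrivacyMode


def _mk_update(cid, values, n, num_classes=4):
    groups = {g: np.asarray(v, dtype=np.float64) for g, v in values.items()}
    protos = PrototypeSet({0: np.zeros(3)}, {0: n})
    return ClientUpdate(cid, ModelState("tiny_cnn", num_classes, groups), protos, n)


class TestFedAvg:
    def test_identical_updates_fixed_point(self):
        vals = {"a": [1.0, -2.0], "b": [0.5]}
        ups = [_mk_update(i, vals, n) for i, n in enumerate([1, 5, 10])]
        out = pf.fedavg(ups)
        for g, v in vals.items():
            np.testing.assert_allclose(out.groups[g], v, rtol=1e-12)

    def test_weighted_scalar_example(self):
        ups = [_mk_update(0, {"w": [0.0]}, 1), _mk_update(1, {"w": [1.0]}, 3)]
        assert pf.fedavg(ups).groups["w"][0] == pytest.approx(0.75)

    def test_matches_brute_force_weighted_mean(self):
        rng = np.random.default_rng(0)
        ns = [3, 7, 11, 2]
        ups = [
            _mk_update(i, {"g1": rng.normal(size=20), "g2": rng.normal(size=5)}, n)
            for i, n in enumerate(ns)
        ]
        out = pf.fedavg(ups)
        # independent oracle: concatenate everything and average explicitly
        total = sum(ns)
        flat = sum(
            (n / total) * np.concatenate([u.model_state.groups["g1"], u.model_state.groups["g2"]])
            for u, n in zip(ups, ns)
        )
        np.testing.assert_allclose(
            np.concatenate([out.groups["g1"], out.groups["g2"]]), flat, rtol=1e-7
        )

    def test_convexity_bounds(self):
        rng = np.random.default_rng(1)
        ups = [_mk_update(i, {"w": rng.normal(size=30)}, int(n)) for i, n in enumerate([1, 4, 9])]
        out = pf.fedavg(ups).groups["w"]
        stack = np.stack([u.model_state.groups["w"] for u in ups])
        assert np.all(out >= stack.min(axis=0) - 1e-12)
        assert np.all(out <= stack.max(axis=0) + 1e-12)

    def test_mismatched_groups_rejected(self):
        with pytest.raises(ValueError):
            pf.fedavg([_mk_update(0, {"a": [1.0]}, 1), _mk_update(1, {"b": [1.0]}, 1)])


class TestAggregatePrototypes:
    def test_count_weighted_hand_example(self):
        a = PrototypeSet({0: np.array([1.0])}, {0: 2})
        b = PrototypeSet({0: np.array([0.5])}, {0: 3})
        out = pf.aggregate_prototypes([a, b])
        assert out.prototypes[0][0] == pytest.approx(0.7)
        assert out.counts[0] == 5

    def test_class_held_by_one_client_passthrough(self):
        a = PrototypeSet({1: np.array([0.2, 0.4])}, {1: 6})
        b = PrototypeSet({2: np.array([0.9, 0.1])}, {2: 3})
        out = pf.aggregate_prototypes([a, b])
        np.testing.assert_allclose(out.prototypes[1], a.prototypes[1], rtol=1e-12)
        np.testing.assert_allclose(out.prototypes[2], b.prototypes[2], rtol=1e-12)

    def test_identical_prototypes_invariant_to_counts(self):
        p = np.array([0.3, -0.7])
        sets = [PrototypeSet({0: p.copy()}, {0: n}) for n in (1, 10, 100)]
        np.testing.assert_allclose(pf.aggregate_prototypes(sets).prototypes[0], p, rtol=1e-12)

    def test_count_conservation(self):
        rng = np.random.default_rng(2)
        sets = [
            PrototypeSet(
                {c: rng.normal(size=4) for c in range(3)}, {c: int(rng.integers(1, 9)) for c in range(3)}
            )
            for _ in range(4)
        ]
        out = pf.aggregate_prototypes(sets)
        for c in range(3):
            assert out.counts[c] == sum(s.counts[c] for s in sets)

    def test_width_mismatch_rejected(self):
        with pytest.raises(ValueError):
            pf.aggregate_prototypes(
                [PrototypeSet({0: np.zeros(3)}, {0: 1}), PrototypeSet({0: np.zeros(4)}, {0: 1})]
            )


@pytest.fixture(scope="module")
def fed_data():
    ds = pf.generate_synthetic_dataset(50, 4, (32, 32), 0.05, seed=11)
    return pf.stratified_split(ds, 0.8, seed=11)


def _small_cfg(mode, seed=11, **kw):
    return pf.ExperimentConfig(
        n_clients=3,
        rounds=2,
        alpha=0.5,
        privacy_mode=PrivacyMode(mode),
        training=pf.TrainingConfig.desk_scale(seed=seed, local_epochs=2),
        seed=seed,
        **kw,
    )


class TestRounds:
    def test_secure_aggregation_transparency(self, fed_data):
        """sa_only must reproduce the no-privacy global states: the pairwise
        masks cancel exactly in the weighted sum."""
        tr, te = fed_data
        res_np, _ = pf.run_experiment(_small_cfg("no_privacy"), tr, te)
        res_sa, _ = pf.run_experiment(_small_cfg("sa_only"), tr, te)
        for a, b in zip(res_np, res_sa):
            fa, fb = a.global_state.flatten(), b.global_state.flatten()
            np.testing.assert_allclose(fb, fa, rtol=1e-6, atol=1e-9)

    def test_dp_without_noise_or_clipping_matches_no_privacy(self, fed_data):
        """sigma = 0 with a clip bound far above the deltas reduces the DP
        path to a no-op."""
        tr, te = fed_data
        res_np, _ = pf.run_experiment(_small_cfg("no_privacy"), tr, te)
        cfg = _small_cfg("dp_only")
        cfg = replace(cfg, dp=pf.DPConfig(clip_norm=1e9, noise_multiplier=0.0))
        res_dp, _ = pf.run_experiment(cfg, tr, te)
        for a, b in zip(res_np, res_dp):
            np.testing.assert_allclose(
                b.global_state.flatten(), a.global_state.flatten(), rtol=1e-12, atol=1e-15
            )

    def test_run_experiment_reproducible_and_writes_csv(self, fed_data, tmp_path):
        tr, te = fed_data
        res1, s1 = pf.run_experiment(_small_cfg("no_privacy"), tr, te, out_dir=tmp_path)
        res2, s2 = pf.run_experiment(_small_cfg("no_privacy"), tr, te)
        assert s1.accuracy == s2.accuracy
        np.testing.assert_array_equal(
            res1[-1].global_state.flatten(), res2[-1].global_state.flatten()
        )
        assert (tmp_path / "federated_learning_results.csv").exists()
        assert (tmp_path / "rounds_no_privacy.csv").exists()

    def test_round_metrics_and_cost_accounting(self, fed_data):
        tr, te = fed_data
        cfg = _small_cfg("sa_only", skip_ratio=0.4)
        results, summary = pf.run_experiment(cfg, tr, te)
        for r in results:
            m = r.metrics
            for v in (m.accuracy, m.precision, m.recall, m.f1):
                assert 0.0 <= v <= 1.0
            expected = (
                pf.per_round_cost(pf.total_params("tiny_cnn", 4), 0.4, True, 1.15)
                * cfg.n_clients
            )
            assert r.comm_MB == pytest.approx(expected)

    def test_prototype_counts_track_training_data(self, fed_data):
        tr, te = fed_data
        results, _ = pf.run_experiment(_small_cfg("no_privacy"), tr, te)
        # round 0: global prototypes aggregate exactly the clients' shards
        assert results[0].global_prototypes.total_count == len(tr)
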