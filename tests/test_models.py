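"""Model registry: inventories, skip plans, freezing and feature extraction."""

import numpy as np
import pytest

import protofed as pf
from protofed.client import local_train
from protofed.models import (
    LayerInventory,
    UnsupportedArchitectureError,
    load_state_into_model,
    state_from_model,
)

# Published ImageNet (1000-class) parameter totals of the registered
# backbone topologies, used as an independent reference for the analytic
# per-stage accounting.
PUBLISHED_IMAGENET_TOTALS = {
    "resnet50": 25_557_032,
    "efficientnet_b0": 5_288_548,
    "convnext": 28_589_128,
    "swin": 28_288_354,
}


class TestInventories:
    @pytest.mark.parametrize("arch,expected", sorted(PUBLISHED_IMAGENET_TOTALS.items()))
    def test_imagenet_totals_match_published(self, arch, expected):
        assert pf.total_params(arch, num_classes=1000) == expected

    def test_resnet50_head_swap_arithmetic(self):
        # swapping the 1000-way linear head (2048*1000+1000) for a 4-way one
        # (2048*4+4) changes the total by exactly the head difference
        full = PUBLISHED_IMAGENET_TOTALS["resnet50"]
        expected = full - (2048 * 1000 + 1000) + (2048 * 4 + 4)
        assert pf.total_params("resnet50", num_classes=4) == expected == 23_516_228

    @pytest.mark.parametrize("arch", pf.ARCHITECTURES)
    def test_head_is_single_and_last(self, arch):
        inv = pf.layer_inventory(arch, 4)
        flags = [h for _, _, h in inv.groups]
        assert flags.count(True) == 1 and flags[-1]

    def test_unknown_architecture(self):
        with pytest.raises(UnsupportedArchitectureError, match="registry"):
            pf.layer_inventory("vgg16", 4)


class TestBuildModel:
    def test_deterministic_initialization(self):
        _, s1 = pf.build_model("tiny_cnn", 4, seed=42)
        _, s2 = pf.build_model("tiny_cnn", 4, seed=42)
        for g in s1.groups:
            assert np.array_equal(s1.groups[g], s2.groups[g])

    def test_large_backbones_are_inventory_only(self):
        with pytest.raises(UnsupportedArchitectureError, match="inventory-only"):
            pf.build_model("resnet50", 4)

    def test_state_roundtrip_through_model(self):
        model, state = pf.build_model("tiny_cnn", 4, seed=0)
        state2 = state_from_model(load_state_into_model(model, state))
        for g in state.groups:
            assert np.array_equal(state.groups[g], state2.groups[g])

    def test_checkpoint_roundtrip(self, tmp_path):
        _, state = pf.build_model("tiny_cnn", 4, seed=3)
        pf.save_checkpoint(state, tmp_path / "ckpt")
        back = pf.load_checkpoint(tmp_path / "ckpt")
        assert back.arch == "tiny_cnn" and back.num_classes == 4
        for g in state.groups:
            assert np.array_equal(state.groups[g], back.groups[g])


class TestSkipPlan:
    def test_hand_traced_greedy_rule(self):
        inv = LayerInventory((("A", 100, False), ("B", 100, False), ("head", 10, True)))
        plan = pf.make_skip_plan(inv, 0.5)
        # after freezing A the cumulative 100 < 105 target, so B freezes too
        assert plan.frozen_groups == {"A", "B"}
        assert plan.trainable_params == 10

    def test_zero_ratio_freezes_nothing(self):
        inv = pf.layer_inventory("resnet50", 4)
        plan = pf.make_skip_plan(inv, 0.0)
        assert not plan.frozen_groups
        assert plan.trainable_params == inv.total_params

    @pytest.mark.parametrize("arch", ["tiny_cnn", "resnet50", "swin"])
    def test_conservation_and_monotonicity(self, arch):
        inv = pf.layer_inventory(arch, 4)
        prev = inv.total_params + 1
        for ratio in (0.0, 0.2, 0.4, 0.6, 0.8):
            plan = pf.make_skip_plan(inv, ratio)
            frozen = sum(n for g, n, _ in inv.groups if g in plan.frozen_groups)
            assert frozen + plan.trainable_params == inv.total_params
            assert plan.trainable_params >= inv.head_params
            assert plan.trainable_params <= prev
            prev = plan.trainable_params

    def test_full_skip_rejected(self):
        with pytest.raises(ValueError):
            pf.make_skip_plan(pf.layer_inventory("tiny_cnn", 4), 1.0)


class TestApplySkipPlan:
    def test_frozen_groups_receive_no_updates(self, small_dataset):
        inv = pf.layer_inventory("tiny_cnn", 4)
        plan = pf.make_skip_plan(inv, 0.9)  # freezes all three conv groups
        assert plan.frozen_groups == {"conv1", "conv2", "conv3"}
        _, state = pf.build_model("tiny_cnn", 4, seed=1)
        upd = local_train(state, plan, small_dataset, pf.TrainingConfig(local_epochs=1))
        for g in ("conv1", "conv2", "conv3"):
            assert np.array_equal(upd.model_state.groups[g], state.groups[g])
        assert not np.array_equal(upd.model_state.groups["head"], state.groups["head"])

    def test_empty_plan_updates_something(self, small_dataset):
        plan = pf.make_skip_plan(pf.layer_inventory("tiny_cnn", 4), 0.0)
        _, state = pf.build_model("tiny_cnn", 4, seed=1)
        upd = local_train(state, plan, small_dataset, pf.TrainingConfig(local_epochs=1))
        assert any(
            not np.array_equal(upd.model_state.groups[g], state.groups[g])
            for g in state.groups
        )

    def test_mismatched_plan_rejected(self):
        model, _ = pf.build_model("tiny_cnn", 4)
        foreign = pf.make_skip_plan(pf.layer_inventory("resnet50", 4), 0.4)
        with pytest.raises(ValueError):
            pf.apply_skip_plan(model, foreign)


class TestFeatureExtraction:
    def test_shape_and_duplicates(self, small_dataset):
        model, _ = pf.build_model("tiny_cnn", 4, seed=0)
        x = small_dataset.pixel_array()[:6]
        feats = pf.extract_features(model, x)
        assert feats.shape == (6, model.feature_width)
        dup = pf.extract_features(model, np.stack([x[0], x[0]]))
        assert np.array_equal(dup[0], dup[1])

    def test_distinct_inputs_distinct_features(self):
        model, _ = pf.build_model("tiny_cnn", 4, seed=0)
        zeros = np.zeros((1, 1, 32, 32))
        ones = np.ones((1, 1, 32, 32))
        f = pf.extract_features(model, np.vstack([zeros, ones]))
        assert not np.allclose(f[0], f[1])

    def test_empty_batch_rejected(self):
        model, _ = pf.build_model("tiny_cnn", 4, seed=0)
        with pytest.raises(ValueError):
            pf.extract_features(model, np.zeros((0, 1, 32, 32)))
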