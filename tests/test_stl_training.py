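"""Loss closed forms, stage bookkeeping, weight carry-over, smoke training."""

import numpy as np
import pytest

from stlseg.data_prep import PatchMaskPair
from stlseg.hierarchy import LabelHierarchy, Stage
from stlseg.stl_training import (
    StageSpec,
    TrainingConfig,
    categorical_accuracy,
    cce_loss,
    evaluate_model,
    run_conventional,
    run_stage,
    run_stl,
)
from stlseg.unet_model import NetworkConfig, build_unet


def blob_pair(target, size=32, seed=0, color=None):
    """A separable fixture: bright square blob on a dark background."""
    rng = np.random.default_rng(seed)
    patch = rng.integers(40, 60, size=(size, size, 3)).astype(np.uint8)
    mask = np.zeros((size, size), dtype=np.int64)
    q = size // 4
    y0, x0 = rng.integers(0, size - 2 * q, size=2)
    if color is None:
        color = [220, 60 + 60 * target, 60]
    patch[y0:y0 + 2 * q, x0:x0 + 2 * q] = color
    mask[y0:y0 + 2 * q, x0:x0 + 2 * q] = target
    return PatchMaskPair(patch=patch, mask=mask, target_class=target,
                         source_id=f"blob{seed}")


class TestCceLoss:
    def test_perfect_one_hot_prediction_is_zero(self):
        truth = np.zeros((2, 2, 3))
        truth[..., 1] = 1.0
        assert cce_loss(truth, truth) == pytest.approx(0.0, abs=1e-9)

    @pytest.mark.parametrize("c", [2, 3, 10])
    def test_uniform_prediction_gives_log_c(self, c):
        pred = np.full((4, 4, c), 1.0 / c)
        truth = np.zeros((4, 4, c))
        truth[..., 0] = 1.0
        assert cce_loss(pred, truth) == pytest.approx(np.log(c), abs=1e-9)

    def test_single_pixel_hand_computation(self):
        pred = np.array([[[0.8, 0.2]]])
        truth = np.array([[[1.0, 0.0]]])
        assert cce_loss(pred, truth) == pytest.approx(-np.log(0.8), abs=1e-9)

    def test_nonnegative(self):
        rng = np.random.default_rng(0)
        logits = rng.normal(size=(3, 3, 4))
        pred = np.exp(logits) / np.exp(logits).sum(-1, keepdims=True)
        truth = np.eye(4)[rng.integers(0, 4, size=(3, 3))]
        assert cce_loss(pred, truth) >= 0.0

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            cce_loss(np.zeros((2, 2, 3)), np.zeros((2, 2, 4)))


class TestCategoricalAccuracy:
    def test_perfect(self):
        pred = np.eye(3)[np.array([[0, 1], [2, 1]])]
        truth = np.array([[0, 1], [2, 1]])
        assert categorical_accuracy(pred, truth) == 1.0

    def test_all_wrong(self):
        pred = np.eye(2)[np.zeros((2, 2), dtype=int)]
        truth = np.ones((2, 2), dtype=int)
        assert categorical_accuracy(pred, truth) == 0.0

    def test_three_of_four(self):
        pred = np.eye(2)[np.array([[0, 1], [1, 1]])]
        truth = np.array([[0, 1], [0, 1]])
        assert categorical_accuracy(pred, truth) == 0.75


TINY_NET = dict(input_size=(32, 32), base_filters=4, depth=2, seed=0)


class TestRunStage:
    def test_degenerate_target_stops_after_first_epoch(self):
        pairs = [blob_pair(1, seed=i) for i in range(4)]
        model = build_unet(NetworkConfig(head_classes=2, **TINY_NET))
        spec = StageSpec(C=2, max_epochs=5, val_accuracy_target=0.0)
        cfg = TrainingConfig(batch_size=2, patch_size=(32, 32), global_seed=0)
        _, result = run_stage(model, spec, pairs[:3], pairs[3:], cfg)
        assert result.epochs_run == 1
        assert result.stop_reason == "target_reached"
        assert len(result.history) == 1

    def test_zero_budget_rejected(self):
        model = build_unet(NetworkConfig(head_classes=2, **TINY_NET))
        spec = StageSpec(C=2, max_epochs=0)
        cfg = TrainingConfig(batch_size=2, patch_size=(32, 32))
        with pytest.raises(ValueError, match="max_epochs"):
            run_stage(model, spec, [blob_pair(1)], [], cfg)

    def test_empty_training_data_rejected(self):
        model = build_unet(NetworkConfig(head_classes=2, **TINY_NET))
        spec = StageSpec(C=2, max_epochs=1)
        cfg = TrainingConfig(batch_size=2, patch_size=(32, 32))
        with pytest.raises(ValueError, match="empty"):
            run_stage(model, spec, [], [], cfg)

    def test_separable_two_class_task_reaches_target(self):
        """A tiny net masters the blob-vs-background task within 10 epochs."""
        pairs = [blob_pair(1, seed=i) for i in range(12)]
        model = build_unet(NetworkConfig(head_classes=2, **TINY_NET))
        spec = StageSpec(C=2, max_epochs=10, val_accuracy_target=0.9)
        cfg = TrainingConfig(batch_size=4, patch_size=(32, 32), global_seed=0,
                             learning_rate=3e-3)
        _, result = run_stage(model, spec, pairs[:9], pairs[9:], cfg)
        assert result.stop_reason == "target_reached"
        assert result.history[-1]["val_accuracy"] >= 0.9


class TestRunStl:
    @staticmethod
    def two_stage_setup():
        # classes 1,2 cluster together vs 3: coarse stage C=3, fine C=4
        pairs = [blob_pair(t, seed=10 * t + i, color=[220, 40 + 25 * t, 40])
                 for t in (1, 2, 3) for i in range(3)]
        hierarchy = LabelHierarchy(stages=[
            Stage(C=3, remap={1: 1, 2: 1, 3: 2}),
            Stage(C=4, remap={1: 1, 2: 2, 3: 3}),
        ])
        cfg = TrainingConfig(batch_size=3, patch_size=(32, 32), global_seed=1)
        net = NetworkConfig(head_classes=4, **TINY_NET)
        return pairs, hierarchy, net, cfg

    def test_budget_count_mismatch_rejected(self):
        pairs, hierarchy, net, cfg = self.two_stage_setup()
        with pytest.raises(ValueError, match="budgets"):
            run_stl(net, hierarchy, pairs, [], cfg, stage_budgets=[1])

    def test_stage_histories_and_head_widths(self):
        pairs, hierarchy, net, cfg = self.two_stage_setup()
        model, results = run_stl(net, hierarchy, pairs[:-2], pairs[-2:], cfg,
                                 stage_budgets=[1, 2], val_accuracy_target=1.0)
        assert [r.epochs_run for r in results] == [1, 2]
        assert model.config.head_classes == 4

    def test_non_head_weights_carried_between_stages(self):
        from stlseg.unet_model import replace_head

        pairs, hierarchy, net, cfg = self.two_stage_setup()
        first = net
        import copy
        first = copy.deepcopy(net)
        first.head_classes = 3
        model = build_unet(first)
        spec = StageSpec(C=3, max_epochs=1, val_accuracy_target=1.0,
                         stage_label_map=hierarchy.stages[0])
        model, _ = run_stage(model, spec, pairs, [], cfg)
        swapped = replace_head(model, 4, seed=5)
        for name, params in model.non_head_parameters().items():
            for key, value in params.items():
                sad = np.abs(value - swapped.parameters()[name][key]).sum()
                assert sad == 0.0

    def test_inherited_head_starts_at_parent_cluster_solution(self):
        from stlseg.stl_training import _inherit_head
        from stlseg.unet_model import build_unet

        pairs, hierarchy, net, cfg = self.two_stage_setup()
        import copy
        coarse_cfg = copy.deepcopy(net)
        coarse_cfg.head_classes = 3
        model = build_unet(coarse_cfg)
        spec = StageSpec(C=3, max_epochs=1, val_accuracy_target=1.0,
                         stage_label_map=hierarchy.stages[0])
        model, _ = run_stage(model, spec, pairs, [], cfg)
        warm = _inherit_head(model, hierarchy.stages[1], hierarchy.stages[0],
                             seed=3)
        # non-head parameters untouched
        for name, params in model.non_head_parameters().items():
            for key, value in params.items():
                np.testing.assert_array_equal(
                    value, warm.parameters()[name][key])
        # sibling channels start near their parent-cluster channel: classes
        # 1 and 2 share coarse cluster 1, class 3 maps to cluster 2
        old = model.conv_registry["head"]
        new = warm.conv_registry["head"]
        for fine_label, coarse_label in [(1, 1), (2, 1), (3, 2), (0, 0)]:
            np.testing.assert_allclose(new.w[fine_label], old.w[coarse_label],
                                       rtol=0.1)
            np.testing.assert_array_equal(new.b[fine_label], old.b[coarse_label])
        # sibling tie is broken: channels 1 and 2 are not identical
        assert np.abs(new.w[1] - new.w[2]).sum() > 0

    def test_single_identity_stage_reduces_to_conventional(self):
        pairs, _, net, cfg = self.two_stage_setup()
        hierarchy = LabelHierarchy(
            stages=[Stage(C=4, remap={1: 1, 2: 2, 3: 3})]
        )
        model, results = run_stl(net, hierarchy, pairs[:-2], pairs[-2:], cfg,
                                 stage_budgets=[2], val_accuracy_target=1.0)
        _, conv_result = run_conventional(net, pairs[:-2], pairs[-2:], cfg,
                                          epochs=2)
        stl_losses = [h["train_loss"] for h in results[0].history]
        conv_losses = [h["train_loss"] for h in conv_result.history]
        assert stl_losses == pytest.approx(conv_losses)


class TestRunConventional:
    def test_single_epoch_history(self):
        pairs = [blob_pair(1, seed=i) for i in range(4)]
        net = NetworkConfig(head_classes=2, **TINY_NET)
        cfg = TrainingConfig(batch_size=2, patch_size=(32, 32), global_seed=0)
        _, result = run_conventional(net, pairs[:3], pairs[3:], cfg, epochs=1)
        assert result.epochs_run == 1 and len(result.history) == 1

    def test_deterministic_given_seed(self):
        pairs = [blob_pair(1, seed=i) for i in range(4)]
        net = NetworkConfig(head_classes=2, **TINY_NET)
        cfg = TrainingConfig(batch_size=2, patch_size=(32, 32), global_seed=3)
        _, a = run_conventional(net, pairs[:3], pairs[3:], cfg, epochs=2)
        _, b = run_conventional(net, pairs[:3], pairs[3:], cfg, epochs=2)
        assert a.history == b.history

    def test_stage_weights_persisted(self, tmp_path):
        pairs = [blob_pair(1, seed=i) for i in range(4)]
        net = NetworkConfig(head_classes=2, **TINY_NET)
        cfg = TrainingConfig(batch_size=2, patch_size=(32, 32))
        _, result = run_conventional(net, pairs[:3], pairs[3:], cfg, epochs=1,
                                     out_dir=tmp_path)
        assert result.weights_ref is not None and result.weights_ref.exists()
        assert (tmp_path / "stage_C2_history.csv").exists()


class TestEvaluateModel:
    def test_metrics_on_constant_background(self):
        net = NetworkConfig(head_classes=2, **TINY_NET)
        model = build_unet(net)
        pairs = [blob_pair(1, seed=0)]
        cfg = TrainingConfig(batch_size=1, patch_size=(32, 32))
        loss, acc = evaluate_model(model, pairs, cfg)
        assert loss > 0.0 and 0.0 <= acc <= 1.0
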