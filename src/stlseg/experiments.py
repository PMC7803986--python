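"""The scaled-down curriculum study.

One self-contained driver reproduces, at desk scale, the study design of
the full pipeline: generate a synthetic family fixture, recover the class
hierarchy from colour-prototype clustering, train one network sequentially
(families + background, then all classes + background) and one
conventionally at a matched total epoch budget, and evaluate both on held
-out trays — final pixel accuracy, the first-epoch training accuracy of the
final stage (the "better start" comparison), and patch-level definiteness.

Problem sizes here are deliberately small (a 3x3-family fixture, a base-8
depth-3 network on 64x64 patches, a few hundred optimizer steps per arm) so
a full multi-seed comparison runs on one CPU in minutes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_prep import crop_roi_patches, resize_pair, split_train_val, augment_flips
from .evaluation import (
    DefinitenessSummary,
    PatchPrediction,
    hit_ratio,
    summarize_definiteness,
)
from .feature_analysis import color_statistic_features
from .hierarchy import build_dendrogram, build_label_hierarchy, cuts_by_greatest_links
from .stl_training import TrainingConfig, evaluate_model, run_conventional, run_stl
from .synthetic_data import SyntheticConfig, generate_dataset, recovery_score
from .unet_model import NetworkConfig

__all__ = ["StudyConditions", "RunResult", "StudyResult", "run_study"]


@dataclass
class StudyConditions:
    """The fixed conditions of the scaled-down comparison."""

    n_train_trays: int = 20
    n_test_trays: int = 18
    patch_size: int = 64
    base_filters: int = 8
    depth: int = 3
    batch_size: int = 6
    learning_rate: float = 3e-3  # a few hundred steps per arm; see methods
    stage_budgets: tuple[int, ...] = (2, 6)
    val_accuracy_target: float = 0.90
    definite_threshold: float = 0.75

    @property
    def total_epochs(self) -> int:
        return int(sum(self.stage_budgets))


@dataclass
class RunResult:
    """Per-seed outcomes of the paired STL / conventional runs."""

    seed: int
    recovery_ari: float
    stage_class_counts: list[int]
    stl_test_accuracy: float
    conventional_test_accuracy: float
    stl_test_loss: float
    conventional_test_loss: float
    stl_final_stage_start_accuracy: float
    conventional_epoch1_accuracy: float
    stl_epochs_run: int
    conventional_epochs_run: int
    stl_definiteness: DefinitenessSummary
    conventional_definiteness: DefinitenessSummary


@dataclass
class StudyResult:
    conditions: StudyConditions
    runs: list[RunResult] = field(default_factory=list)


def _definiteness(model, pairs, threshold):
    preds = []
    for pair in pairs:
        labels = model.predict_labels(pair.patch)[0]
        preds.append(PatchPrediction(predicted_mask=labels,
                                     truth_mask=pair.mask,
                                     target_class=pair.target_class))
    return summarize_definiteness(preds, threshold)


def run_single(seed: int, conditions: StudyConditions | None = None) -> RunResult:
    """One paired comparison at the given seed."""
    cond = conditions or StudyConditions()
    size = (cond.patch_size, cond.patch_size)

    cfg = SyntheticConfig(seed=seed)
    trays, designed = generate_dataset(cfg, cond.n_train_trays, seed=seed)
    test_trays, _ = generate_dataset(cfg, cond.n_test_trays, seed=seed + 100)
    pairs = [resize_pair(p, size) for p in crop_roi_patches(trays)]
    test_pairs = [resize_pair(p, size) for p in crop_roi_patches(test_trays)]
    splits = split_train_val(augment_flips(pairs), 0.2, seed=seed)

    by_class: dict[int, list] = {}
    for p in pairs:
        by_class.setdefault(p.target_class, []).append(p)
    obs = color_statistic_features(by_class)
    dend = build_dendrogram(obs)
    parts = cuts_by_greatest_links(dend, cfg.n_families - 1)
    ari = recovery_score(designed, parts[-1])
    hierarchy = build_label_hierarchy([parts[-1]], obs.class_order)

    net = NetworkConfig(input_size=size, base_filters=cond.base_filters,
                        depth=cond.depth, head_classes=cfg.n_classes + 1,
                        seed=seed)
    tc = TrainingConfig(batch_size=cond.batch_size, patch_size=size,
                        learning_rate=cond.learning_rate, global_seed=seed)

    stl_model, stl_results = run_stl(
        net, hierarchy, splits.train, splits.validation, tc,
        stage_budgets=list(cond.stage_budgets),
        val_accuracy_target=cond.val_accuracy_target,
        head_init="inherit",
    )
    stl_loss, stl_acc = evaluate_model(stl_model, test_pairs, tc)

    conv_model, conv_result = run_conventional(
        net, splits.train, splits.validation, tc, epochs=cond.total_epochs,
    )
    conv_loss, conv_acc = evaluate_model(conv_model, test_pairs, tc)

    return RunResult(
        seed=seed,
        recovery_ari=ari,
        stage_class_counts=hierarchy.stage_class_counts(),
        stl_test_accuracy=stl_acc,
        conventional_test_accuracy=conv_acc,
        stl_test_loss=stl_loss,
        conventional_test_loss=conv_loss,
        stl_final_stage_start_accuracy=stl_results[-1].history[0]["train_accuracy"],
        conventional_epoch1_accuracy=conv_result.history[0]["train_accuracy"],
        stl_epochs_run=sum(r.epochs_run for r in stl_results),
        conventional_epochs_run=conv_result.epochs_run,
        stl_definiteness=_definiteness(stl_model, test_pairs,
                                       cond.definite_threshold),
        conventional_definiteness=_definiteness(conv_model, test_pairs,
                                                cond.definite_threshold),
    )


def run_study(seed: int = 1, n_seeds: int = 3,
              conditions: StudyConditions | None = None) -> StudyResult:
    """Paired comparisons across ``n_seeds`` consecutive seeds."""
    cond = conditions or StudyConditions()
    result = StudyResult(conditions=cond)
    for i in range(n_seeds):
        result.runs.append(run_single(seed + i, cond))
    return result
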