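"""Conventional and sequential (curriculum) training.

Sequential transfer learning (STL) trains one network through a sequence of
progressively finer label sets derived from the dendrogram cuts: at each
stage the classifier head is replaced by a freshly initialised C-way 1x1
convolution, all other weights are carried over, the training masks are
remapped through the stage's label map, and the network trains until either
a validation-accuracy target (default 90%) is reached or the stage's epoch
budget is exhausted — whichever comes first.

The loss is per-pixel categorical cross-entropy (softmax over class
channels, truth-weighted log-probability) reduced to a per-pixel mean so
values are comparable across patch sizes; the optimizer is Adam with its
cited defaults (lr 1e-3, beta1 0.9, beta2 0.999, eps 1e-8).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data_prep import PatchMaskPair
from .hierarchy import LabelHierarchy, Stage, remap_mask
from .unet_model import (
    HEAD_REINIT_SCALE,
    NetworkConfig,
    SegmentationModel,
    build_unet,
    replace_head,
    save_model,
    softmax_channels,
)

__all__ = [
    "StageSpec",
    "StageResult",
    "TrainingConfig",
    "cce_loss",
    "categorical_accuracy",
    "run_stage",
    "run_stl",
    "run_conventional",
    "evaluate_model",
]

_EPS = 1e-12


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class StageSpec:
    """One training round: head width, budget and early-advance rule."""

    C: int
    max_epochs: int
    val_accuracy_target: float = 0.90
    stage_label_map: Stage | None = None  # None = identity relabelling
    head_seed: int = 0

    def __post_init__(self) -> None:
        if self.C < 2:
            raise ValueError("C must be >= 2")
        if not 0.0 <= self.val_accuracy_target <= 1.0:
            raise ValueError("val_accuracy_target must lie in [0, 1]")


@dataclass
class StageResult:
    """Per-epoch history and stopping bookkeeping for one stage."""

    history: list[dict] = field(default_factory=list)
    epochs_run: int = 0
    stop_reason: str = ""  # target_reached | budget_exhausted
    weights_ref: Path | None = None
    loss_reduction: str = "per_pixel_mean"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.history)


@dataclass
class TrainingConfig:
    """Optimisation hyper-parameters (batch 20 and 256x256 at full scale)."""

    batch_size: int = 20
    patch_size: tuple[int, int] = (256, 256)
    learning_rate: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    global_seed: int = 0

    def __post_init__(self) -> None:
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


# ---------------------------------------------------------------------------
# Loss and metric (channel-last public API)
# ---------------------------------------------------------------------------

def cce_loss(prediction: np.ndarray, truth: np.ndarray) -> float:
    """Per-pixel mean categorical cross-entropy.

    ``prediction`` holds per-pixel softmax probabilities and ``truth`` the
    one-hot ground truth, both channel-last and of identical shape.  Perfect
    one-hot predictions give 0; uniform predictions over c channels give
    ln(c).
    """
    prediction = np.asarray(prediction, dtype=np.float64)
    truth = np.asarray(truth, dtype=np.float64)
    if prediction.shape != truth.shape:
        raise ValueError(
            f"prediction shape {prediction.shape} != truth shape {truth.shape}"
        )
    per_pixel = -(truth * np.log(np.clip(prediction, _EPS, None))).sum(axis=-1)
    return float(per_pixel.mean())


def categorical_accuracy(prediction: np.ndarray, truth: np.ndarray) -> float:
    """Fraction of pixels whose argmax channel equals the true label.

    ``prediction`` is channel-last scores/probabilities; ``truth`` is either
    an integer label raster of the matching spatial shape or one-hot.
    """
    prediction = np.asarray(prediction)
    truth = np.asarray(truth)
    pred_labels = prediction.argmax(axis=-1)
    true_labels = truth.argmax(axis=-1) if truth.shape == prediction.shape else truth
    if pred_labels.shape != true_labels.shape:
        raise ValueError(
            f"shape mismatch: {pred_labels.shape} vs {true_labels.shape}"
        )
    return float((pred_labels == true_labels).mean())


# ---------------------------------------------------------------------------
# Optimiser
# ---------------------------------------------------------------------------

class _Adam:
    def __init__(self, model: SegmentationModel, cfg: TrainingConfig):
        self.cfg = cfg
        self.t = 0
        self.m = {
            name: {k: np.zeros_like(v) for k, v in layer.params.items()}
            for name, layer in model.conv_registry.items()
        }
        self.v = {
            name: {k: np.zeros_like(v) for k, v in layer.params.items()}
            for name, layer in model.conv_registry.items()
        }

    def step(self, model: SegmentationModel) -> None:
        c = self.cfg
        self.t += 1
        bc1 = 1.0 - c.beta1 ** self.t
        bc2 = 1.0 - c.beta2 ** self.t
        for name, layer in model.conv_registry.items():
            for k, g in layer.grads.items():
                m = self.m[name][k]
                v = self.v[name][k]
                m *= c.beta1
                m += (1 - c.beta1) * g
                v *= c.beta2
                v += (1 - c.beta2) * g * g
                layer.params[k] -= (
                    c.learning_rate * (m / bc1) / (np.sqrt(v / bc2) + c.eps)
                )


# ---------------------------------------------------------------------------
# Data marshalling
# ---------------------------------------------------------------------------

def _stack_pairs(
    pairs: list[PatchMaskPair], stage: Stage | None, expected_size: tuple[int, int]
) -> tuple[np.ndarray, np.ndarray]:
    xs, ys = [], []
    for pair in pairs:
        if pair.patch.shape[:2] != expected_size:
            raise ValueError(
                f"patch {pair.source_id} has size {pair.patch.shape[:2]}, "
                f"expected {expected_size}; resize pairs before training"
            )
        mask = pair.mask if stage is None else remap_mask(pair.mask, stage)
        xs.append(pair.patch)
        ys.append(mask)
    return np.stack(xs), np.stack(ys).astype(np.int64)


def _forward_metrics(
    model: SegmentationModel, X: np.ndarray, Y: np.ndarray, batch_size: int
) -> tuple[float, float]:
    """Loss and accuracy over a dataset, evaluated in mini-batches."""
    total_nll = 0.0
    total_correct = 0
    total_pix = 0
    for start in range(0, len(X), batch_size):
        xb = X[start:start + batch_size]
        yb = Y[start:start + batch_size]
        logits = model.forward_logits(model._to_nchw(xb))
        p = softmax_channels(logits)
        idx = np.ogrid[tuple(slice(s) for s in yb.shape)]
        ptrue = p[idx[0], yb, idx[1], idx[2]]
        total_nll += float(-np.log(np.clip(ptrue, _EPS, None)).sum())
        total_correct += int((logits.argmax(axis=1) == yb).sum())
        total_pix += yb.size
    return total_nll / total_pix, total_correct / total_pix


# ---------------------------------------------------------------------------
# Training rounds
# ---------------------------------------------------------------------------

def run_stage(
    model: SegmentationModel,
    spec: StageSpec,
    train: list[PatchMaskPair],
    val: list[PatchMaskPair],
    cfg: TrainingConfig,
    out_dir: str | Path | None = None,
) -> tuple[SegmentationModel, StageResult]:
    """Train one curriculum stage; returns the trained model and its history.

    The head is replaced first if its width differs from ``spec.C``; masks
    are remapped through the stage label map; validation loss/accuracy are
    evaluated at the end of every epoch and the stage advances early once
    the validation-accuracy target is met.
    """
    if spec.max_epochs < 1:
        raise ValueError("max_epochs must be >= 1")
    if not train:
        raise ValueError("training data is empty")
    if model.config.head_classes != spec.C:
        model = replace_head(model, spec.C, spec.head_seed)
    size = model.config.input_size
    Xtr, Ytr = _stack_pairs(train, spec.stage_label_map, size)
    Xva, Yva = _stack_pairs(val, spec.stage_label_map, size) if val else (None, None)
    if Ytr.max() >= spec.C:
        raise ValueError(
            f"stage labels reach {Ytr.max()} but the head has only {spec.C} channels"
        )

    opt = _Adam(model, cfg)
    rng = np.random.default_rng([cfg.global_seed, spec.C])
    result = StageResult()
    for epoch in range(1, spec.max_epochs + 1):
        order = rng.permutation(len(Xtr))
        ep_nll, ep_correct, ep_pix = 0.0, 0, 0
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            xb = Xtr[idx]
            yb = Ytr[idx]
            logits = model.forward_logits(model._to_nchw(xb))
            p = softmax_channels(logits)
            og = np.ogrid[tuple(slice(s) for s in yb.shape)]
            ptrue = p[og[0], yb, og[1], og[2]]
            ep_nll += float(-np.log(np.clip(ptrue, _EPS, None)).sum())
            ep_correct += int((logits.argmax(axis=1) == yb).sum())
            ep_pix += yb.size
            # softmax + CCE gradient: (p - onehot) / n_pixels
            dlogits = p.copy()
            dlogits[og[0], yb, og[1], og[2]] -= 1.0
            dlogits /= yb.size
            model.backward(dlogits.astype(np.float32))
            opt.step(model)
        if Xva is not None:
            val_loss, val_acc = _forward_metrics(model, Xva, Yva, cfg.batch_size)
        else:
            val_loss, val_acc = float("nan"), float("nan")
        result.history.append(
            {
                "epoch": epoch,
                "train_loss": ep_nll / ep_pix,
                "train_accuracy": ep_correct / ep_pix,
                "val_loss": val_loss,
                "val_accuracy": val_acc,
            }
        )
        result.epochs_run = epoch
        if Xva is not None and val_acc >= spec.val_accuracy_target:
            result.stop_reason = "target_reached"
            break
    else:
        result.stop_reason = "budget_exhausted"

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        result.weights_ref = save_model(model, out_dir / f"stage_C{spec.C}.h5")
        result.to_frame().to_csv(out_dir / f"stage_C{spec.C}_history.csv", index=False)
    return model, result


def _inherit_head(model: SegmentationModel, fine: Stage, coarse: Stage,
                  seed: int) -> SegmentationModel:
    """Head for a finer stage warm-started from the parent-cluster head.

    Each fine-stage output channel copies the head weights of the cluster
    that contains it at the coarser stage (background keeps background), so
    the new stage starts at the coarse solution; a small seeded jitter
    breaks the tie between siblings.
    """
    old_head = model.conv_registry[model.HEAD_NAME]
    new = replace_head(model, fine.C, seed)
    head = new.conv_registry[new.HEAD_NAME]
    parent = {0: 0}
    for cls, fine_label in fine.remap.items():
        parent[fine_label] = coarse.remap[cls]
    jitter = np.random.default_rng(seed)
    for fine_label, coarse_label in parent.items():
        head.w[fine_label] = old_head.w[coarse_label] * (
            1.0 + HEAD_REINIT_SCALE * jitter.normal(size=old_head.w[coarse_label].shape)
        ).astype(head.w.dtype)
        head.b[fine_label] = old_head.b[coarse_label]
    return new


def run_stl(
    config: NetworkConfig,
    hierarchy: LabelHierarchy,
    train: list[PatchMaskPair],
    val: list[PatchMaskPair],
    cfg: TrainingConfig,
    stage_budgets: list[int],
    val_accuracy_target: float = 0.90,
    head_init: str = "fresh",
    out_dir: str | Path | None = None,
) -> tuple[SegmentationModel, list[StageResult]]:
    """Sequential transfer learning over all hierarchy stages.

    One network is built once and carried through the stages; at each stage
    the head is re-initialised to the stage's C and the masks are remapped
    through the stage's label map.  ``stage_budgets`` gives the per-stage
    epoch budget (the full-scale schedule is 10,10,10,10,20 for the stages
    C = 3,4,5,17,66).

    ``head_init`` selects how each new stage's classifier starts: ``fresh``
    (a seeded small-magnitude draw) or ``inherit`` (warm-started from the
    parent cluster's head channel, so the stage begins at the coarse
    solution — useful when epochs hold too few optimizer steps to re-align
    a fresh head).
    """
    stages = list(hierarchy)
    if len(stage_budgets) != len(stages):
        raise ValueError(
            f"{len(stage_budgets)} budgets for {len(stages)} stages"
        )
    if head_init not in ("fresh", "inherit"):
        raise ValueError(f"unknown head_init {head_init!r}")
    import copy as _copy

    first_cfg = _copy.deepcopy(config)
    first_cfg.head_classes = stages[0].C
    model = build_unet(first_cfg)
    results: list[StageResult] = []
    for i, (stage, budget) in enumerate(zip(stages, stage_budgets)):
        head_seed = cfg.global_seed + 1000 * (i + 1)
        if i > 0 and head_init == "inherit":
            model = _inherit_head(model, stage, stages[i - 1], head_seed)
        spec = StageSpec(
            C=stage.C,
            max_epochs=budget,
            val_accuracy_target=val_accuracy_target,
            stage_label_map=stage,
            head_seed=head_seed,
        )
        model, result = run_stage(model, spec, train, val, cfg, out_dir=out_dir)
        results.append(result)
    return model, results


def run_conventional(
    config: NetworkConfig,
    train: list[PatchMaskPair],
    val: list[PatchMaskPair],
    cfg: TrainingConfig,
    epochs: int,
    val_accuracy_target: float = 1.0,
    out_dir: str | Path | None = None,
) -> tuple[SegmentationModel, StageResult]:
    """Single-round training on the full label set (the baseline)."""
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    model = build_unet(config)
    spec = StageSpec(
        C=config.head_classes,
        max_epochs=epochs,
        val_accuracy_target=val_accuracy_target,
        stage_label_map=None,
        head_seed=config.seed,
    )
    return run_stage(model, spec, train, val, cfg, out_dir=out_dir)


def evaluate_model(
    model: SegmentationModel,
    pairs: list[PatchMaskPair],
    cfg: TrainingConfig,
    stage: Stage | None = None,
) -> tuple[float, float]:
    """(mean per-pixel CCE, categorical accuracy) of a model on a pair list."""
    if not pairs:
        raise ValueError("no pairs to evaluate")
    X, Y = _stack_pairs(pairs, stage, model.config.input_size)
    return _forward_metrics(model, X, Y, cfg.batch_size)
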