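"""Class-prototype feature construction.

Each food class is summarised by one feature observation: a few training
patches per class are sampled, bottleneck feature volumes are extracted for
each, every volume is reduced to a vector, and the per-class vectors are
averaged into one row of an observation matrix (classes x features).  That
matrix is what the hierarchical clustering operates on, optionally after a
PCA projection.

Two volume-to-vector paths exist:

* ``summarize_volume_mean`` — per-channel spatial mean (global average
  pooling), turning an H'xW'xD volume into D features.  This is the default
  for U-Net-style bottlenecks (D = 1024 at full size).
* ``reduce_deep_volume`` — for wide backbone features such as a 32x32x4096
  volume: the volume is re-arranged depth-wise into an (H'*W') x D matrix,
  the D columns are PCA-projected down to ``n_components`` (default 50),
  and the result is serialised row-major into a vector of length
  H'*W'*n_components (51,200 for the 32x32x4096 case) instead of the
  4,194,304-element raw serialisation.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.decomposition import PCA

from .data_prep import PatchMaskPair

__all__ = [
    "FeatureVolume",
    "ObservationMatrix",
    "sample_class_patches",
    "summarize_volume_mean",
    "reduce_deep_volume",
    "serialized_length",
    "build_observation_matrix",
    "pca_scores",
    "color_statistic_features",
    "class_prototype_matrix",
    "save_observation_matrix",
    "load_observation_matrix",
]


@dataclass
class FeatureVolume:
    """One 3D activation volume (H' x W' x D) tagged with its provenance."""

    values: np.ndarray
    source_class: int = 0
    source_patch: str = ""

    def __post_init__(self) -> None:
        if self.values.ndim != 3:
            raise ValueError("feature volume must be 3-dimensional (H', W', D)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("feature volume contains non-finite values")


@dataclass
class ObservationMatrix:
    """One feature row per class; the input to hierarchical clustering."""

    rows: np.ndarray          # (n_classes, F)
    class_order: list[int]    # ascending class ids, one per row
    feature_origin: str = "unet_mean"  # unet_mean | deep_reduced | raw_serialized | color_stats | pca_scores

    def __post_init__(self) -> None:
        if self.rows.ndim != 2:
            raise ValueError("observation matrix must be 2-dimensional")
        if len(self.class_order) != self.rows.shape[0]:
            raise ValueError("class_order length must equal the number of rows")
        if len(set(self.class_order)) != len(self.class_order):
            raise ValueError("class_order contains duplicate class ids")
        if not np.all(np.isfinite(self.rows)):
            raise ValueError("observation matrix contains missing/non-finite values")


# ---------------------------------------------------------------------------
# Patch sampling
# ---------------------------------------------------------------------------

def sample_class_patches(
    train: list[PatchMaskPair], k: int, seed: int
) -> dict[int, list[PatchMaskPair]]:
    """Sample ``k`` training patches per class, deterministically.

    Sampling is without replacement when a class has at least ``k`` patches
    and with replacement otherwise.  Classes are processed in ascending id
    order from one seeded generator, so the selection is reproducible.
    """
    by_class: dict[int, list[PatchMaskPair]] = {}
    for pair in train:
        by_class.setdefault(pair.target_class, []).append(pair)
    rng = np.random.default_rng(seed)
    out: dict[int, list[PatchMaskPair]] = {}
    for class_id in sorted(by_class):
        pool = by_class[class_id]
        if not pool:
            raise ValueError(f"class {class_id} has no training patches")
        idx = rng.choice(len(pool), size=k, replace=len(pool) < k)
        out[class_id] = [pool[i] for i in idx]
    if not out:
        raise ValueError("no training patches supplied")
    return out


# ---------------------------------------------------------------------------
# Volume -> vector
# ---------------------------------------------------------------------------

def summarize_volume_mean(volume: FeatureVolume) -> np.ndarray:
    """Global average pooling: one mean per channel (vector of length D)."""
    v = volume.values
    if v.size == 0:
        raise ValueError("cannot summarise an empty feature volume")
    return v.mean(axis=(0, 1))


def serialized_length(volume: FeatureVolume) -> int:
    """Element count of the raw depth-wise serialisation (H' * W' * D)."""
    return int(np.prod(volume.values.shape))


def reduce_deep_volume(volume: FeatureVolume, n_components: int = 50) -> np.ndarray:
    """PCA-reduce a wide volume depth-wise, then serialise.

    The H'xW'xD volume becomes an (H'*W') x D matrix (row-major spatial
    order), its D columns are projected onto the top ``n_components``
    principal axes fitted on that same matrix, and the (H'*W') x
    n_components result is flattened row-major.
    """
    v = volume.values
    hp, wp, d = v.shape
    if n_components > d:
        raise ValueError(
            f"n_components={n_components} exceeds feature depth {d}"
        )
    mat = v.reshape(hp * wp, d)
    pca = PCA(n_components=n_components, svd_solver="auto", random_state=0)
    scores = pca.fit_transform(mat)
    return scores.reshape(-1)


# ---------------------------------------------------------------------------
# Observation matrix
# ---------------------------------------------------------------------------

def build_observation_matrix(
    per_class_vectors: dict[int, list[np.ndarray]],
    feature_origin: str = "unet_mean",
) -> ObservationMatrix:
    """Average each class's vectors into one prototype row.

    Rows are ordered by ascending class id.  All vectors must share one
    length.
    """
    if not per_class_vectors:
        raise ValueError("no per-class vectors supplied")
    lengths = {
        len(v) for vectors in per_class_vectors.values() for v in vectors
    }
    if len(lengths) != 1:
        raise ValueError(f"inconsistent vector lengths: {sorted(lengths)}")
    class_order = sorted(per_class_vectors)
    rows = np.stack(
        [np.mean(per_class_vectors[c], axis=0) for c in class_order]
    ).astype(np.float64)
    return ObservationMatrix(rows=rows, class_order=class_order,
                             feature_origin=feature_origin)


def pca_scores(
    obs: ObservationMatrix,
    variance_target: float | None = None,
    n_components: int | None = None,
) -> ObservationMatrix:
    """Project class prototypes onto principal axes.

    Either retain enough components to reach ``variance_target`` (a
    proportion of explained variance) or a fixed ``n_components``; with
    neither argument, all nontrivial components are kept.
    """
    if obs.rows.shape[0] < 2:
        raise ValueError("PCA needs at least 2 observations")
    if variance_target is not None and n_components is not None:
        raise ValueError("give either variance_target or n_components, not both")
    max_comp = min(obs.rows.shape[0] - 1, obs.rows.shape[1])
    if n_components is not None:
        k: float | int = min(n_components, max_comp)
    elif variance_target is not None:
        k = variance_target  # sklearn picks the smallest count reaching it
    else:
        k = max_comp
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(obs.rows)
    return replace(obs, rows=scores, feature_origin="pca_scores")


# ---------------------------------------------------------------------------
# Convenience feature paths
# ---------------------------------------------------------------------------

def color_statistic_features(
    pairs_by_class: dict[int, list[PatchMaskPair]]
) -> ObservationMatrix:
    """Simple per-class colour prototypes: mean and std of foreground RGB.

    A lightweight, model-free observation matrix (6 features per class) for
    diagnosing whether the designed visual hierarchy is recoverable at all.
    """
    vectors: dict[int, list[np.ndarray]] = {}
    for class_id, pairs in pairs_by_class.items():
        for pair in pairs:
            fg = pair.mask == pair.target_class
            if not fg.any():
                continue
            px = pair.patch[fg].astype(np.float64)
            vectors.setdefault(class_id, []).append(
                np.concatenate([px.mean(axis=0), px.std(axis=0)])
            )
    if not vectors:
        raise ValueError("no foreground pixels in any patch")
    return build_observation_matrix(vectors, feature_origin="color_stats")


def class_prototype_matrix(
    model,
    train: list[PatchMaskPair],
    k: int = 3,
    seed: int = 0,
) -> ObservationMatrix:
    """End-to-end prototype construction from a trained model.

    Samples ``k`` patches per class, taps the bottleneck for each, applies
    global average pooling and averages per class.
    """
    from .unet_model import extract_bottleneck

    sampled = sample_class_patches(train, k=k, seed=seed)
    vectors: dict[int, list[np.ndarray]] = {}
    for class_id, patches in sampled.items():
        for pair in patches:
            vol = extract_bottleneck(model, pair.patch)
            vol.source_class = class_id
            vol.source_patch = pair.source_id
            vectors.setdefault(class_id, []).append(summarize_volume_mean(vol))
    return build_observation_matrix(vectors, feature_origin="unet_mean")


# ---------------------------------------------------------------------------
# Persistence: CSV with class-id header + YAML sidecar
# ---------------------------------------------------------------------------

def save_observation_matrix(obs: ObservationMatrix, path: str | Path) -> Path:
    path = Path(path)
    df = pd.DataFrame(obs.rows.T, columns=[str(c) for c in obs.class_order])
    df.to_csv(path, index=False)
    path.with_suffix(".yaml").write_text(
        yaml.safe_dump({"feature_origin": obs.feature_origin,
                        "class_order": list(obs.class_order)})
    )
    return path


def load_observation_matrix(path: str | Path) -> ObservationMatrix:
    path = Path(path)
    df = pd.read_csv(path)
    meta = yaml.safe_load(path.with_suffix(".yaml").read_text())
    return ObservationMatrix(
        rows=df.to_numpy().T,
        class_order=[int(c) for c in df.columns],
        feature_origin=meta.get("feature_origin", "unet_mean"),
    )
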