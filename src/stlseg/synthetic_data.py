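"""Synthetic tray fixtures with a designed visual class hierarchy.

The generator emulates the structure of canteen-tray segmentation data:
gray-tray backgrounds carrying food-like elliptical regions, one class per
region, with tight bounding boxes and an integer label mask.  Classes are
organised into visually correlated families: every family has a base colour
placed on a chroma circle (spacing controlled by the between-family spread
``family_color_spread``), and each class offsets that base colour by a
Gaussian with the much smaller within-family spread ``class_color_spread``.
Band-limited texture noise and per-pixel noise are added on top.  Because
the family structure is planted, hierarchy-recovery tests can score a
recovered partition against the designed one with the adjusted Rand index.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from skimage.transform import resize as _sk_resize
from sklearn.metrics import adjusted_rand_score

from .data_prep import TrayRecord
from .hierarchy import Partition

__all__ = [
    "SyntheticConfig",
    "DesignedHierarchy",
    "generate_tray",
    "generate_dataset",
    "recovery_score",
]

_GRAY = 110.0  # tray background level
_CENTER = 128.0  # chroma circle centre

# orthonormal chroma axes spanning the plane of constant luminance in RGB
_CHROMA_U = np.array([1.0, -1.0, 0.0]) / np.sqrt(2.0)
_CHROMA_V = np.array([1.0, 1.0, -2.0]) / np.sqrt(6.0)


@dataclass
class SyntheticConfig:
    """Parameters of the designed family/class hierarchy.

    ``family_color_spread`` (the chroma-circle radius, 8-bit colour units)
    should dominate ``class_color_spread`` (per-channel Gaussian sigma) for
    the hierarchy to be recoverable; the recovery tests assert this regime,
    not the constructor.
    """

    n_families: int = 3
    classes_per_family: int = 3
    image_size: tuple[int, int] = (128, 128)
    blobs_per_tray: int = 2
    family_color_spread: float = 60.0
    class_color_spread: float = 6.0
    texture_scales: list[int] = field(default_factory=lambda: [4, 8])
    texture_amplitude: float = 3.0
    pixel_noise: float = 3.0
    seed: int = 0

    @property
    def n_classes(self) -> int:
        return self.n_families * self.classes_per_family


@dataclass
class DesignedHierarchy:
    """Ground-truth family membership (class id -> family id)."""

    family_of: dict[int, int]

    def as_partition(self) -> Partition:
        return Partition(
            assignment=dict(self.family_of),
            n_clusters=len(set(self.family_of.values())),
            cut_height=float("nan"),
        )

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(
            json.dumps({"family_of": {str(k): v for k, v in self.family_of.items()}})
        )
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "DesignedHierarchy":
        payload = json.loads(Path(path).read_text())
        return cls(family_of={int(k): v for k, v in payload["family_of"].items()})


def designed_hierarchy(cfg: SyntheticConfig) -> DesignedHierarchy:
    """Classes 1..n in blocks of ``classes_per_family`` per family."""
    return DesignedHierarchy(
        family_of={
            c: (c - 1) // cfg.classes_per_family + 1
            for c in range(1, cfg.n_classes + 1)
        }
    )


def class_color(cfg: SyntheticConfig, class_id: int) -> np.ndarray:
    """Deterministic RGB fill colour: family base + class offset.

    Family bases sit on a chroma circle of radius ``family_color_spread``;
    the class offset is Gaussian with sigma ``class_color_spread`` drawn
    from a stream keyed by (seed, class id).
    """
    family = (class_id - 1) // cfg.classes_per_family
    theta = 2.0 * np.pi * family / cfg.n_families
    base = _CENTER + cfg.family_color_spread * (
        np.cos(theta) * _CHROMA_U + np.sin(theta) * _CHROMA_V
    )
    rng = np.random.default_rng([cfg.seed, 7919, class_id])
    return base + rng.normal(0.0, cfg.class_color_spread, size=3)


def _texture(cfg: SyntheticConfig, rng: np.random.Generator,
             shape: tuple[int, int]) -> np.ndarray:
    """Band-limited noise: low-resolution noise up-sampled per scale."""
    tex = np.zeros(shape)
    for scale in cfg.texture_scales:
        low = rng.normal(0.0, 1.0, size=(max(shape[0] // scale, 1),
                                         max(shape[1] // scale, 1)))
        tex += _sk_resize(low, shape, order=1, anti_aliasing=False)
    if cfg.texture_scales:
        tex *= cfg.texture_amplitude / np.sqrt(len(cfg.texture_scales))
    return tex


def generate_tray(
    cfg: SyntheticConfig,
    tray_seed: int,
    classes: list[int] | None = None,
) -> TrayRecord:
    """Render one tray with ``blobs_per_tray`` superelliptical food regions.

    Blobs are placed one per cell of a regular grid (jittered), so they
    never overlap; ``classes`` fixes the per-blob class ids (random
    otherwise).  Deterministic given (cfg.seed, tray_seed).
    """
    H, W = cfg.image_size
    rng = np.random.default_rng([cfg.seed, tray_seed])
    image = np.clip(
        _GRAY + rng.normal(0.0, cfg.pixel_noise, size=(H, W, 3)), 0, 255
    )
    mask = np.zeros((H, W), dtype=np.int64)
    boxes: list[tuple[int, tuple[int, int, int, int]]] = []

    n_blobs = cfg.blobs_per_tray
    if classes is not None and len(classes) != n_blobs:
        raise ValueError("classes list length must equal blobs_per_tray")
    if n_blobs > 0:
        g = int(np.ceil(np.sqrt(n_blobs)))
        cell_h, cell_w = H // g, W // g
        if min(cell_h, cell_w) < 16:
            raise ValueError(
                f"cannot pack {n_blobs} blobs with margins into {H}x{W}"
            )
        cells = [(r, c) for r in range(g) for c in range(g)][:n_blobs]
        yy, xx = np.mgrid[0:H, 0:W]
        for i, (r, c) in enumerate(cells):
            class_id = (
                classes[i] if classes is not None
                else int(rng.integers(1, cfg.n_classes + 1))
            )
            a = rng.uniform(0.26, 0.40) * cell_w
            b = rng.uniform(0.26, 0.40) * cell_h
            p = rng.uniform(1.5, 3.0)
            cy = r * cell_h + cell_h / 2 + rng.uniform(-0.05, 0.05) * cell_h
            cx = c * cell_w + cell_w / 2 + rng.uniform(-0.05, 0.05) * cell_w
            member = (
                np.abs((xx - cx) / a) ** p + np.abs((yy - cy) / b) ** p
            ) <= 1.0
            color = class_color(cfg, class_id)
            tex = _texture(cfg, rng, (H, W))
            fill = (
                color[None, None, :]
                + tex[:, :, None]
                + rng.normal(0.0, cfg.pixel_noise, size=(H, W, 3))
            )
            image[member] = np.clip(fill[member], 0, 255)
            mask[member] = class_id
            ys, xs = np.nonzero(member)
            boxes.append(
                (class_id, (int(xs.min()), int(ys.min()),
                            int(xs.max()) + 1, int(ys.max()) + 1))
            )
    return TrayRecord(
        tray_id=f"tray{tray_seed:05d}",
        image=image.astype(np.uint8),
        mask=mask,
        boxes=boxes,
    )


def generate_dataset(
    cfg: SyntheticConfig, n_trays: int, seed: int
) -> tuple[list[TrayRecord], DesignedHierarchy]:
    """Generate trays covering every class, plus the designed hierarchy.

    Blob classes cycle through seeded permutations of the class list, so
    class frequencies are near-uniform and coverage is guaranteed whenever
    ``n_trays * blobs_per_tray >= n_classes``.
    """
    if n_trays < 1:
        raise ValueError("n_trays must be >= 1")
    total_blobs = n_trays * cfg.blobs_per_tray
    if total_blobs < cfg.n_classes:
        raise ValueError(
            f"{n_trays} trays x {cfg.blobs_per_tray} blobs cannot cover "
            f"{cfg.n_classes} classes"
        )
    rng = np.random.default_rng([cfg.seed, seed, 104729])
    sequence: list[int] = []
    while len(sequence) < total_blobs:
        sequence.extend(rng.permutation(np.arange(1, cfg.n_classes + 1)).tolist())
    trays = []
    for t in range(n_trays):
        classes = sequence[t * cfg.blobs_per_tray:(t + 1) * cfg.blobs_per_tray]
        trays.append(generate_tray(cfg, tray_seed=seed * 4099 + t, classes=classes))
    return trays, designed_hierarchy(cfg)


def recovery_score(designed: DesignedHierarchy, partition: Partition) -> float:
    """Adjusted Rand index between designed families and a recovered cut."""
    if set(designed.family_of) != set(partition.assignment):
        raise ValueError("designed hierarchy and partition cover different classes")
    classes = sorted(designed.family_of)
    truth = [designed.family_of[c] for c in classes]
    found = [partition.assignment[c] for c in classes]
    return float(adjusted_rand_score(truth, found))
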