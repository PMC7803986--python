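"""Tray-to-patch data preparation.

Annotated tray images (RGB image, integer label mask, per-item bounding
boxes) are converted into single-class region-of-interest (ROI) patch-mask
pairs: one patch per bounding box, with any pixel inside the box that does
not belong to the box's class relabelled as background (0).  On top of the
crops this module implements the augmentation and bookkeeping rules used for
training: a four-fold flip expansion of the training set, a seeded
train/validation split, a rotation-based round-robin expansion of deficient
test classes, and steps-per-epoch arithmetic.

Bounding boxes are half-open pixel rectangles [x0, x1) x [y0, y1) in 0-based
coordinates: ``x`` indexes columns (width) and ``y`` rows (height).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import imageio.v3 as iio
from skimage.transform import resize as _sk_resize

__all__ = [
    "TrayRecord",
    "PatchMaskPair",
    "DatasetSplits",
    "crop_roi_patches",
    "resize_pair",
    "augment_flips",
    "split_train_val",
    "augment_test_to_min",
    "steps_per_epoch",
    "read_manifest",
    "write_manifest",
    "write_patch_cache",
    "read_patch_cache",
    "FLIP_TRANSFORMS",
    "TEST_EXPANSION_TRANSFORMS",
    "apply_transform",
]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class TrayRecord:
    """One annotated tray: RGB image, label mask and per-item boxes.

    ``boxes`` is a list of ``(class_id, (x0, y0, x1, y1))`` with half-open
    0-based pixel rectangles; class id 0 (background) never appears as a box
    class.
    """

    tray_id: str
    image: np.ndarray  # (H, W, 3) uint8
    mask: np.ndarray   # (H, W) integer labels, 0 = background
    boxes: list[tuple[int, tuple[int, int, int, int]]] = field(default_factory=list)

    def validate(self) -> None:
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise ValueError(f"tray {self.tray_id}: image must be HxWx3")
        if self.mask.shape != self.image.shape[:2]:
            raise ValueError(f"tray {self.tray_id}: mask/image shape mismatch")
        for class_id, _ in self.boxes:
            if class_id <= 0:
                raise ValueError(
                    f"tray {self.tray_id}: box class_id must be positive, got {class_id}"
                )


@dataclass
class PatchMaskPair:
    """A single-class ROI patch and its mask (values in {0, target_class})."""

    patch: np.ndarray  # (h, w, 3)
    mask: np.ndarray   # (h, w)
    target_class: int
    source_id: str     # tray id + box index, e.g. "tray003:box2"
    transform: str = "identity"

    @property
    def provenance(self) -> tuple[str, str]:
        return (self.source_id, self.transform)


@dataclass
class DatasetSplits:
    train: list[PatchMaskPair]
    validation: list[PatchMaskPair]
    test: list[PatchMaskPair]
    split_seed: int


# ---------------------------------------------------------------------------
# ROI cropping
# ---------------------------------------------------------------------------

def crop_roi_patches(trays: list[TrayRecord]) -> list[PatchMaskPair]:
    """Crop one single-class patch-mask pair per bounding box.

    Within each crop, mask pixels whose tray-mask value differs from the
    box's class (other foods as well as true background) are set to 0, so
    every output mask takes values in ``{0, target_class}`` only.  Trays with
    a box outside the image bounds are rejected with a descriptive error.
    """
    pairs: list[PatchMaskPair] = []
    for tray in trays:
        tray.validate()
        H, W = tray.mask.shape
        for i, (class_id, (x0, y0, x1, y1)) in enumerate(tray.boxes):
            if not (0 <= x0 < x1 <= W and 0 <= y0 < y1 <= H):
                raise ValueError(
                    f"tray {tray.tray_id}: box {i} ({x0},{y0},{x1},{y1}) "
                    f"outside image bounds {W}x{H}"
                )
            patch = tray.image[y0:y1, x0:x1].copy()
            sub = tray.mask[y0:y1, x0:x1]
            mask = np.where(sub == class_id, class_id, 0).astype(tray.mask.dtype)
            pairs.append(
                PatchMaskPair(
                    patch=patch,
                    mask=mask,
                    target_class=int(class_id),
                    source_id=f"{tray.tray_id}:box{i}",
                )
            )
    return pairs


def resize_pair(pair: PatchMaskPair, size: tuple[int, int]) -> PatchMaskPair:
    """Resample a pair to ``(height, width)``.

    The patch is bilinearly interpolated; the mask uses nearest-neighbour
    resampling so values stay in {0, target_class}.
    """
    h, w = size
    if h <= 0 or w <= 0:
        raise ValueError(f"size must be positive, got {size}")
    if pair.patch.shape[:2] == (h, w):
        return pair
    patch = _sk_resize(
        pair.patch, (h, w), order=1, preserve_range=True, anti_aliasing=False
    )
    patch = np.clip(np.rint(patch), 0, 255).astype(pair.patch.dtype)
    mask = _sk_resize(
        pair.mask, (h, w), order=0, preserve_range=True, anti_aliasing=False
    ).astype(pair.mask.dtype)
    return replace(pair, patch=patch, mask=mask)


# ---------------------------------------------------------------------------
# Augmentation
# ---------------------------------------------------------------------------

def _hflip(a: np.ndarray) -> np.ndarray:
    return a[:, ::-1].copy()


def _vflip(a: np.ndarray) -> np.ndarray:
    return a[::-1].copy()


def _rot90cw(a: np.ndarray, k: int) -> np.ndarray:
    # numpy rotates counter-clockwise for positive k
    return np.rot90(a, -k).copy()


# identity + horizontal flip + vertical flip + both: the 4x training expansion
FLIP_TRANSFORMS: dict[str, object] = {
    "identity": lambda a: a.copy(),
    "hflip": _hflip,
    "vflip": _vflip,
    "hvflip": lambda a: _hflip(_vflip(a)),
}

# fixed per-patch draw order for the test-set expansion: three clockwise
# rotations, three clockwise rotations after a vertical flip, then the flip
TEST_EXPANSION_TRANSFORMS: tuple[str, ...] = (
    "rot90",
    "rot180",
    "rot270",
    "vflip+rot90",
    "vflip+rot180",
    "vflip+rot270",
    "vflip",
)

_ALL_TRANSFORMS: dict[str, object] = {
    **FLIP_TRANSFORMS,
    "rot90": lambda a: _rot90cw(a, 1),
    "rot180": lambda a: _rot90cw(a, 2),
    "rot270": lambda a: _rot90cw(a, 3),
    "vflip+rot90": lambda a: _rot90cw(_vflip(a), 1),
    "vflip+rot180": lambda a: _rot90cw(_vflip(a), 2),
    "vflip+rot270": lambda a: _rot90cw(_vflip(a), 3),
}


def apply_transform(pair: PatchMaskPair, name: str) -> PatchMaskPair:
    """Apply a named geometric transform identically to patch and mask."""
    try:
        fn = _ALL_TRANSFORMS[name]
    except KeyError:
        raise KeyError(f"unknown transform {name!r}") from None
    return replace(pair, patch=fn(pair.patch), mask=fn(pair.mask), transform=name)


def augment_flips(pairs: list[PatchMaskPair]) -> list[PatchMaskPair]:
    """Four-fold expansion: identity, horizontal, vertical and combined flip."""
    out: list[PatchMaskPair] = []
    for pair in pairs:
        for name in FLIP_TRANSFORMS:
            out.append(apply_transform(pair, name))
    return out


def split_train_val(
    pairs: list[PatchMaskPair], val_fraction: float, seed: int
) -> DatasetSplits:
    """Shuffle and hold out ``round(val_fraction * n)`` pairs for validation.

    Deterministic given the seed; rounding is half-up so 9020 pairs at 0.2
    give a 7216/1804 split.
    """
    if not pairs:
        raise ValueError("cannot split an empty list of pairs")
    if not 0.0 < val_fraction < 1.0:
        raise ValueError(f"val_fraction must be in (0, 1), got {val_fraction}")
    n = len(pairs)
    n_val = int(math.floor(val_fraction * n + 0.5))
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    val = [pairs[i] for i in order[:n_val]]
    train = [pairs[i] for i in order[n_val:]]
    return DatasetSplits(train=train, validation=val, test=[], split_seed=seed)


def augment_test_to_min(
    pairs_by_class: dict[int, list[PatchMaskPair]], minimum: int
) -> dict[int, list[PatchMaskPair]]:
    """Bring every class up to ``minimum`` patches by rotation-based expansion.

    Deficient classes are expanded by cycling round-robin through the
    original patches, drawing each patch's transforms in the fixed order
    ``TEST_EXPANSION_TRANSFORMS`` (at most 7 new patches per original), so
    the augmentation load is spread as evenly as possible across originals.
    """
    if minimum < 1:
        raise ValueError("minimum must be >= 1")
    out: dict[int, list[PatchMaskPair]] = {}
    for class_id, originals in pairs_by_class.items():
        if len(originals) >= minimum:
            out[class_id] = list(originals)
            continue
        needed = minimum - len(originals)
        if minimum > 8 * len(originals):
            raise ValueError(
                f"class {class_id}: cannot reach {minimum} patches from "
                f"{len(originals)} originals (at most 7 new per original)"
            )
        expanded = list(originals)
        next_transform = [0] * len(originals)
        i = 0
        while needed > 0:
            idx = i % len(originals)
            name = TEST_EXPANSION_TRANSFORMS[next_transform[idx]]
            next_transform[idx] += 1
            expanded.append(apply_transform(originals[idx], name))
            needed -= 1
            i += 1
        out[class_id] = expanded
    return out


def steps_per_epoch(n_pairs: int, batch_size: int) -> int:
    """Number of optimizer steps per epoch: ceil(n_pairs / batch_size)."""
    if n_pairs <= 0 or batch_size <= 0:
        raise ValueError("n_pairs and batch_size must be positive")
    return -(-n_pairs // batch_size)


# ---------------------------------------------------------------------------
# External interfaces: JSON-lines manifest and patch cache
# ---------------------------------------------------------------------------

def write_manifest(trays: list[TrayRecord], out_dir: str | Path) -> Path:
    """Write trays as PNGs plus a JSON-lines manifest; returns manifest path.

    One line per tray: ``{"tray_id", "image", "mask", "boxes"}`` with boxes as
    ``[class_id, x0, y0, x1, y1]`` (half-open, 0-based) and paths relative to
    the manifest.
    """
    out_dir = Path(out_dir)
    (out_dir / "images").mkdir(parents=True, exist_ok=True)
    (out_dir / "masks").mkdir(parents=True, exist_ok=True)
    manifest = out_dir / "manifest.jsonl"
    with open(manifest, "w") as fh:
        for tray in trays:
            img_rel = f"images/{tray.tray_id}.png"
            mask_rel = f"masks/{tray.tray_id}.png"
            iio.imwrite(out_dir / img_rel, tray.image.astype(np.uint8))
            iio.imwrite(out_dir / mask_rel, tray.mask.astype(np.uint8))
            rec = {
                "tray_id": tray.tray_id,
                "image": img_rel,
                "mask": mask_rel,
                "boxes": [[c, *box] for c, box in tray.boxes],
            }
            fh.write(json.dumps(rec) + "\n")
    return manifest


def read_manifest(manifest: str | Path) -> list[TrayRecord]:
    """Load a JSON-lines manifest written by :func:`write_manifest`."""
    manifest = Path(manifest)
    base = manifest.parent
    trays: list[TrayRecord] = []
    with open(manifest) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            rec = json.loads(line)
            image = np.asarray(iio.imread(base / rec["image"]))
            mask = np.asarray(iio.imread(base / rec["mask"])).astype(np.int64)
            boxes = [(int(b[0]), tuple(int(v) for v in b[1:5])) for b in rec["boxes"]]
            trays.append(
                TrayRecord(tray_id=rec["tray_id"], image=image, mask=mask, boxes=boxes)
            )
    return trays


def write_patch_cache(
    pairs_by_split: dict[str, list[PatchMaskPair]], out_dir: str | Path
) -> Path:
    """Persist patch-mask pairs as paired PNGs plus a CSV index."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    counter = 0
    for split, pairs in pairs_by_split.items():
        for pair in pairs:
            stem = f"{counter:06d}"
            iio.imwrite(out_dir / f"{stem}_patch.png", pair.patch.astype(np.uint8))
            iio.imwrite(out_dir / f"{stem}_mask.png", pair.mask.astype(np.uint8))
            rows.append(
                {
                    "stem": stem,
                    "split": split,
                    "target_class": pair.target_class,
                    "source_id": pair.source_id,
                    "transform": pair.transform,
                }
            )
            counter += 1
    index = out_dir / "index.csv"
    pd.DataFrame(rows).to_csv(index, index=False)
    return index


def read_patch_cache(index: str | Path) -> dict[str, list[PatchMaskPair]]:
    """Load a patch cache written by :func:`write_patch_cache`."""
    index = Path(index)
    base = index.parent
    df = pd.read_csv(index, dtype={"stem": str})
    out: dict[str, list[PatchMaskPair]] = {}
    for row in df.itertuples():
        patch = np.asarray(iio.imread(base / f"{row.stem}_patch.png"))
        mask = np.asarray(iio.imread(base / f"{row.stem}_mask.png")).astype(np.int64)
        pair = PatchMaskPair(
            patch=patch,
            mask=mask,
            target_class=int(row.target_class),
            source_id=str(row.source_id),
            transform=str(row.transform),
        )
        out.setdefault(str(row.split), []).append(pair)
    return out
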