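"""Dendrograms, graph cuts and nested label hierarchies.

Class prototypes are grouped by agglomerative hierarchical clustering into a
binary merge tree (dendrogram).  Cutting the tree just below its greatest
link heights produces a coarse-to-fine sequence of partitions of the food
classes; each partition becomes one curriculum stage in which all classes of
a cluster share a label.  Background is never clustered: it is appended as
label 0 at every stage, so a partition into ``n`` clusters yields a stage
with ``C = n + 1`` classes, and the final stage is the identity relabelling
of the full class set.

Link heights are assumed monotone non-decreasing in merge order, which
holds for the exposed linkage criteria (single, complete, average, ward).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage as _scipy_linkage

from .feature_analysis import ObservationMatrix

__all__ = [
    "Dendrogram",
    "Partition",
    "Stage",
    "LabelHierarchy",
    "build_dendrogram",
    "cut_at_height",
    "cuts_by_greatest_links",
    "cuts_by_target_counts",
    "build_label_hierarchy",
    "remap_mask",
    "save_dendrogram",
    "load_dendrogram",
]

LINKAGE_METHODS = ("single", "complete", "average", "ward")


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass
class Dendrogram:
    """Binary merge tree in scipy linkage form.

    ``links[j] = (left, right, height, size)`` merges nodes ``left`` and
    ``right`` into node ``n_leaves + j``; node ids below ``n_leaves`` are
    leaves, in the order of ``leaf_labels``.
    """

    n_leaves: int
    links: np.ndarray          # (n_leaves - 1, 4) float
    leaf_labels: list[int]

    def __post_init__(self) -> None:
        self.links = np.asarray(self.links, dtype=float)
        if self.links.shape != (self.n_leaves - 1, 4):
            raise ValueError(
                f"a dendrogram over {self.n_leaves} leaves needs exactly "
                f"{self.n_leaves - 1} links, got {self.links.shape[0]}"
            )
        children = self.links[:, :2].astype(int).ravel()
        if len(set(children.tolist())) != len(children):
            raise ValueError("a node is referenced more than once as a child")

    @property
    def heights(self) -> np.ndarray:
        return self.links[:, 2]


@dataclass
class Partition:
    """A flat clustering of the class ids (cluster ids contiguous from 1)."""

    assignment: dict[int, int]
    n_clusters: int
    cut_height: float

    def clusters(self) -> dict[int, list[int]]:
        out: dict[int, list[int]] = {}
        for class_id, cl in self.assignment.items():
            out.setdefault(cl, []).append(class_id)
        return out


@dataclass
class Stage:
    """One curriculum stage: C-way labelling including background 0."""

    C: int
    remap: dict[int, int]


@dataclass
class LabelHierarchy:
    """Ordered nested stages from coarse to fine; background fixed at 0."""

    stages: list[Stage]
    background_label: int = 0

    def __iter__(self):
        return iter(self.stages)

    def __len__(self) -> int:
        return len(self.stages)

    def stage_class_counts(self) -> list[int]:
        return [s.C for s in self.stages]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        payload = {
            "stages": [
                {"C": s.C, "remap": {str(k): v for k, v in s.remap.items()}}
                for s in self.stages
            ]
        }
        path.write_text(json.dumps(payload, indent=2))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "LabelHierarchy":
        payload = json.loads(Path(path).read_text())
        stages = [
            Stage(C=int(s["C"]), remap={int(k): int(v) for k, v in s["remap"].items()})
            for s in payload["stages"]
        ]
        return cls(stages=stages)


# ---------------------------------------------------------------------------
# Clustering and cuts
# ---------------------------------------------------------------------------

def build_dendrogram(
    obs: ObservationMatrix,
    linkage: str = "ward",
    metric: str = "euclidean",
) -> Dendrogram:
    """Agglomerative clustering of the class prototypes.

    Ward linkage with Euclidean distance is the default (stable, balanced
    groups); single/complete/average with any scipy metric are accepted.
    """
    if obs.rows.shape[0] < 2:
        raise ValueError("clustering needs at least 2 observations")
    if linkage not in LINKAGE_METHODS:
        raise ValueError(f"linkage must be one of {LINKAGE_METHODS}, got {linkage!r}")
    if linkage == "ward" and metric != "euclidean":
        raise ValueError("ward linkage requires the euclidean metric")
    Z = _scipy_linkage(obs.rows, method=linkage, metric=metric)
    return Dendrogram(
        n_leaves=obs.rows.shape[0], links=Z, leaf_labels=list(obs.class_order)
    )


class _DSU:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        self.parent[self.find(a)] = self.find(b)


def _partition_from_included(dend: Dendrogram, included: np.ndarray,
                             cut_height: float) -> Partition:
    n = dend.n_leaves
    dsu = _DSU(2 * n - 1)
    for j in range(n - 1):
        if included[j]:
            a, b = int(dend.links[j, 0]), int(dend.links[j, 1])
            dsu.union(a, n + j)
            dsu.union(b, n + j)
    roots: dict[int, int] = {}
    assignment: dict[int, int] = {}
    for leaf in range(n):
        r = dsu.find(leaf)
        if r not in roots:
            roots[r] = len(roots) + 1  # contiguous ids ordered by first leaf
        assignment[dend.leaf_labels[leaf]] = roots[r]
    return Partition(assignment=assignment, n_clusters=len(roots),
                     cut_height=float(cut_height))


def cut_at_height(dendrogram: Dendrogram, h: float) -> Partition:
    """Cluster leaves connected by links of height <= h.

    The number of clusters equals 1 + the number of links above ``h``.
    """
    if h < 0:
        raise ValueError("cut height must be non-negative")
    included = dendrogram.heights <= h
    return _partition_from_included(dendrogram, included, h)


def cuts_by_greatest_links(dendrogram: Dendrogram, k: int) -> list[Partition]:
    """Cut just below each of the ``k`` greatest link heights.

    Tied links at the same height are severed together.  Partitions are
    returned coarse to fine; duplicates (possible when fewer than ``k``
    distinct heights exist) are collapsed.
    """
    if not 1 <= k <= dendrogram.n_leaves - 1:
        raise ValueError(
            f"k must be in [1, {dendrogram.n_leaves - 1}], got {k}"
        )
    distinct = np.unique(dendrogram.heights)[::-1]  # descending
    partitions: list[Partition] = []
    for h in distinct[:k]:
        included = dendrogram.heights < h  # strictly below: severs ties at h
        part = _partition_from_included(dendrogram, included, h)
        if partitions and part.assignment == partitions[-1].assignment:
            continue
        partitions.append(part)
    return partitions


def cuts_by_target_counts(
    dendrogram: Dendrogram, targets: list[int]
) -> list[Partition]:
    """Cut to explicit per-stage cluster counts.

    For each target the coarsest greatest-links cut with at least that many
    clusters is chosen (the cut at the smallest height achieving >= the
    count).  Targets must be increasing.
    """
    if sorted(targets) != list(targets):
        raise ValueError("target cluster counts must be increasing")
    all_cuts = cuts_by_greatest_links(dendrogram, dendrogram.n_leaves - 1)
    partitions: list[Partition] = []
    for t in targets:
        match = next((p for p in all_cuts if p.n_clusters >= t), None)
        if match is None:
            raise ValueError(
                f"no cut reaches {t} clusters (max {all_cuts[-1].n_clusters})"
            )
        if partitions and match.assignment == partitions[-1].assignment:
            continue
        partitions.append(match)
    return partitions


# ---------------------------------------------------------------------------
# Label hierarchies
# ---------------------------------------------------------------------------

def _check_nested(coarse: Partition, fine: Partition) -> None:
    """Every fine cluster must lie inside one coarse cluster."""
    rep: dict[int, int] = {}
    for class_id, fine_cl in fine.assignment.items():
        coarse_cl = coarse.assignment[class_id]
        if fine_cl in rep and rep[fine_cl] != coarse_cl:
            raise ValueError(
                "partitions are not nested: fine cluster "
                f"{fine_cl} spans coarse clusters {rep[fine_cl]} and {coarse_cl}"
            )
        rep[fine_cl] = coarse_cl


def build_label_hierarchy(
    partitions: list[Partition], original_labels: list[int]
) -> LabelHierarchy:
    """Turn coarse-to-fine partitions into nested curriculum stages.

    Each partition becomes a stage with ``C = n_clusters + 1`` (background
    appended as label 0); a final identity stage over the original labels is
    appended.  Partitions must be ordered by increasing cluster count, cover
    every original label, and be mutually nested.
    """
    labels = sorted(original_labels)
    counts = [p.n_clusters for p in partitions]
    if counts != sorted(counts):
        raise ValueError("partitions must be ordered by increasing n_clusters")
    for part in partitions:
        if sorted(part.assignment) != labels:
            raise ValueError("partition does not cover the original labels")
    for coarse, fine in zip(partitions, partitions[1:]):
        _check_nested(coarse, fine)
    stages = [
        Stage(C=p.n_clusters + 1, remap=dict(p.assignment)) for p in partitions
    ]
    identity = Stage(C=len(labels) + 1, remap={c: c for c in labels})
    # drop a trailing all-singletons stage that would duplicate the identity C
    while stages and stages[-1].C >= identity.C:
        stages.pop()
    stages.append(identity)
    cs = [s.C for s in stages]
    if any(b <= a for a, b in zip(cs, cs[1:])):
        raise ValueError(f"stage class counts must strictly increase, got {cs}")
    return LabelHierarchy(stages=stages)


def remap_mask(mask: np.ndarray, stage: Stage) -> np.ndarray:
    """Element-wise relabelling of a mask through one stage; 0 is preserved."""
    values = np.unique(mask)
    out = np.zeros_like(mask)
    for v in values:
        if v == 0:
            continue
        if int(v) not in stage.remap:
            raise KeyError(f"mask label {int(v)} is not in the stage remap")
        out[mask == v] = stage.remap[int(v)]
    return out


# ---------------------------------------------------------------------------
# Persistence
# ---------------------------------------------------------------------------

def save_dendrogram(dend: Dendrogram, path: str | Path) -> Path:
    """Write the linkage as a 4-column CSV; leaf labels in a header comment."""
    path = Path(path)
    df = pd.DataFrame(dend.links, columns=["left", "right", "height", "size"])
    with open(path, "w") as fh:
        fh.write("# leaf_labels: " + ",".join(map(str, dend.leaf_labels)) + "\n")
        df.to_csv(fh, index=False)
    return path


def load_dendrogram(path: str | Path) -> Dendrogram:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline()
        labels = [int(x) for x in header.split(":", 1)[1].split(",")]
        df = pd.read_csv(fh)
    return Dendrogram(n_leaves=len(labels), links=df.to_numpy(),
                      leaf_labels=labels)
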