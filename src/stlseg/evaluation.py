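"""Prediction definiteness metrics.

Single-class test patches are scored by their pixel-level *hit ratio*: the
fraction of ground-truth target-class pixels that the model predicted as
that class.  A patch is a *definite* prediction when its hit ratio strictly
exceeds a threshold (0.75 by default), otherwise *indefinite*.  Summaries
aggregate definite/indefinite counts and mean prediction quality per class,
*split cases* compare which classes remain predominantly indefinite under
two models, and top-k-plus-Other reports compress a patch's predicted label
distribution the way the qualitative figures do.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PatchPrediction",
    "DefinitenessSummary",
    "hit_ratio",
    "classify_definiteness",
    "summarize_definiteness",
    "split_cases",
    "top_response_report",
    "save_report",
]

DEFINITE_THRESHOLD = 0.75


@dataclass
class PatchPrediction:
    """A predicted mask next to its single-class ground truth."""

    predicted_mask: np.ndarray
    truth_mask: np.ndarray
    target_class: int
    per_class_pixel_counts: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.predicted_mask.shape != self.truth_mask.shape:
            raise ValueError("predicted and truth masks must share shape")
        if not self.per_class_pixel_counts:
            labels, counts = np.unique(self.predicted_mask, return_counts=True)
            self.per_class_pixel_counts = {
                int(l): int(c) for l, c in zip(labels, counts)
            }


@dataclass
class DefinitenessSummary:
    n_definite: int
    n_indefinite: int
    mean_quality: float
    per_class: dict[int, tuple[int, int]]  # class -> (n_definite, patch count)

    @property
    def total(self) -> int:
        return self.n_definite + self.n_indefinite

    def definite_fraction(self) -> float:
        return self.n_definite / self.total


def hit_ratio(pred: PatchPrediction) -> float:
    """Correctly predicted target-class pixels / target-class truth pixels.

    Background agreement is deliberately excluded from the denominator: the
    patches are single-class by construction, so quality is measured against
    the food region only.
    """
    fg = pred.truth_mask == pred.target_class
    n_fg = int(fg.sum())
    if n_fg == 0:
        raise ValueError(
            f"no ground-truth pixels of class {pred.target_class} in patch"
        )
    n_hit = int((pred.predicted_mask[fg] == pred.target_class).sum())
    return n_hit / n_fg


def classify_definiteness(
    ratio: float, threshold: float = DEFINITE_THRESHOLD
) -> str:
    """'definite' iff the hit ratio strictly exceeds the threshold."""
    if not 0.0 <= ratio <= 1.0:
        raise ValueError(f"hit ratio must lie in [0, 1], got {ratio}")
    return "definite" if ratio > threshold else "indefinite"


def summarize_definiteness(
    preds: list[PatchPrediction], threshold: float = DEFINITE_THRESHOLD
) -> DefinitenessSummary:
    """Aggregate hit ratios into definite/indefinite counts per class."""
    if not preds:
        raise ValueError("no predictions to summarise")
    n_def = 0
    ratios = []
    per_class: dict[int, list[int]] = {}
    for pred in preds:
        r = hit_ratio(pred)
        ratios.append(r)
        definite = classify_definiteness(r, threshold) == "definite"
        n_def += definite
        cls = per_class.setdefault(pred.target_class, [0, 0])
        cls[0] += definite
        cls[1] += 1
    return DefinitenessSummary(
        n_definite=n_def,
        n_indefinite=len(preds) - n_def,
        mean_quality=float(np.mean(ratios)),
        per_class={c: (v[0], v[1]) for c, v in per_class.items()},
    )


def split_cases(
    summary_a: DefinitenessSummary,
    summary_b: DefinitenessSummary,
    rule: float = 0.5,
) -> tuple[set[int], set[int], set[int]]:
    """Venn-style comparison of predominantly indefinite classes.

    A class is a split case for a model when its indefinite patch fraction
    exceeds ``rule``.  Returns (only_a, only_b, both).
    """
    if set(summary_a.per_class) != set(summary_b.per_class):
        raise ValueError("summaries cover different class sets")

    def _split(summary: DefinitenessSummary) -> set[int]:
        out = set()
        for c, (n_def, n_tot) in summary.per_class.items():
            if (n_tot - n_def) / n_tot > rule:
                out.add(c)
        return out

    a, b = _split(summary_a), _split(summary_b)
    return a - b, b - a, a & b


def top_response_report(
    pred: PatchPrediction, top_k: int = 2
) -> list[tuple[int | str, Fraction]]:
    """Top-k predicted labels by pixel share, remainder lumped as 'Other'.

    Fractions are exact rationals on pixel counts and sum to 1; ties at the
    rank boundary are broken by ascending label id.
    """
    counts = pred.per_class_pixel_counts
    total = sum(counts.values())
    ranked = sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    top = ranked[:top_k]
    other = sum(c for _, c in ranked[top_k:])
    report: list[tuple[int | str, Fraction]] = [
        (label, Fraction(c, total)) for label, c in top
    ]
    report.append(("Other", Fraction(other, total)))
    return report


def save_report(
    summary: DefinitenessSummary,
    ratios: list[float] | None,
    path: str | Path,
) -> Path:
    """Write the evaluation report as JSON plus a per-class CSV."""
    path = Path(path)
    payload = {
        "n_definite": summary.n_definite,
        "n_indefinite": summary.n_indefinite,
        "definite_fraction": summary.definite_fraction(),
        "mean_quality": summary.mean_quality,
        "per_class": {
            str(c): {"n_definite": d, "n_patches": t}
            for c, (d, t) in sorted(summary.per_class.items())
        },
    }
    if ratios is not None:
        payload["per_patch_hit_ratios"] = list(map(float, ratios))
    path.write_text(json.dumps(payload, indent=2))
    rows = [
        {"class": c, "n_definite": d, "n_patches": t}
        for c, (d, t) in sorted(summary.per_class.items())
    ]
    pd.DataFrame(rows).to_csv(path.with_suffix(".csv"), index=False)
    return path
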