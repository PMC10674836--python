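"""Threshold selection by exhaustive 2-D ROC grid search.

Every candidate cutoff pair (a, b) defines the step-1 classifier
"irregular iff count_rr <= a AND svd_ratio <= b".  The default grid is the
set of observed feature values per axis (plus +inf), which covers every
threshold-equivalence class, so the exhaustive scan provably finds the
optimum.  The best pair minimises the Euclidean distance to the perfect
ROC corner — sensitivity 1, false-positive rate 0 — i.e.
distance^2 = (1 - Se)^2 + (1 - Sp)^2.  Ties break toward the smaller
(count_rr, then svd_ratio) cutoffs for determinism.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Sequence

import numpy as np

from .core import ValidationError
from .features import FeatureVector


@dataclass(frozen=True)
class ROCPoint:
    count_rr_thr: float
    svd_ratio_thr: float
    sensitivity: float
    specificity: float

    @property
    def distance(self) -> float:
        return sqrt((1 - self.sensitivity) ** 2 + (1 - self.specificity) ** 2)


def _as_arrays(
    features: Sequence[FeatureVector], labels: Sequence[bool]
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c = np.array([f.count_rr for f in features], dtype=float)
    s = np.array([f.svd_ratio for f in features], dtype=float)
    y = np.asarray(labels, dtype=bool)
    if y.size != c.size:
        raise ValidationError("features and labels must align")
    return c, s, y


def roc_grid(
    features: Sequence[FeatureVector],
    labels: Sequence[bool],
    grid_count_rr: Sequence[float] | None = None,
    grid_svd: Sequence[float] | None = None,
) -> list[ROCPoint]:
    """One ROC point per grid pair; prediction = both features <= cutoffs.

    ``labels`` is True for AF.  Both classes must be present.
    """
    c, s, y = _as_arrays(features, labels)
    if y.all() or not y.any():
        raise ValidationError("degenerate labels: need both classes")
    ga = (
        np.array(sorted(set(np.append(c, np.inf))))
        if grid_count_rr is None
        else np.asarray(grid_count_rr, dtype=float)
    )
    gb = (
        np.array(sorted(set(np.append(s, np.inf))))
        if grid_svd is None
        else np.asarray(grid_svd, dtype=float)
    )
    n_pos = int(y.sum())
    n_neg = int(y.size - n_pos)
    points = []
    for a in ga:
        ca = c <= a
        for b in gb:
            pred = ca & (s <= b)
            tp = int(np.sum(pred & y))
            fp = int(np.sum(pred & ~y))
            points.append(
                ROCPoint(
                    float(a), float(b),
                    sensitivity=tp / n_pos,
                    specificity=(n_neg - fp) / n_neg,
                )
            )
    return points


def select_thresholds(roc: Sequence[ROCPoint]) -> ROCPoint:
    """Minimal distance to the perfect corner; lexicographic tie-break."""
    if not roc:
        raise ValidationError("empty ROC list")
    return min(roc, key=lambda p: (p.distance, p.count_rr_thr, p.svd_ratio_thr))


def tune_thresholds(
    features: Sequence[FeatureVector], labels: Sequence[bool]
) -> ROCPoint:
    """Grid search + selection in one call."""
    return select_thresholds(roc_grid(features, labels))
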