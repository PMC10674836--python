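"""Detecting regularity within irregularity: constrained Lorenz clustering.

Premature beats and grouped beating produce a small number of discrete,
well-separated point clouds in the Lorenz plot, while atrial fibrillation
produces one diffuse cloud.  k-means partitions are searched from ``k_max``
down to 2 and a partition is accepted only if every cluster is compact
(member-to-centroid radius <= ``max_cluster_width``), populated (>=
``min_cluster_size`` members, so a single aberrant interval cannot veto
AF), and genuinely separated from every other cluster.

Separation is measured as the minimum distance between members of
*different* clusters — an empty-margin criterion.  A contiguous AF cloud
can always be split into parts whose centroids are far apart, but it can
never be split across a 0.4 s empty gap, so the gap criterion is what
actually prevents accidental cluster detection in fibrillation while the
tight clouds of ectopic rhythms (separated by real empty space) pass it.

``cluster_count`` is the largest accepted k, or 1 when no partition is
accepted — meaning no regular structure was found.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans

from .core import InvalidSignal
from .features import LorenzPoints


@dataclass(frozen=True)
class ClusterParams:
    """Cluster-acceptance geometry (seconds on both Lorenz axes)."""

    min_separation: float = 0.4
    max_cluster_width: float = 0.5
    k_max: int = 4
    min_cluster_size: int = 2
    n_restarts: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.min_separation <= 0:
            raise ValueError("min_separation must be positive")
        if self.k_max < 2:
            raise ValueError("k_max must be >= 2")


@dataclass(frozen=True)
class ClusterResult:
    cluster_count: int
    centroids: np.ndarray  # (cluster_count, 2)
    assignments: np.ndarray  # per-point cluster index
    accepted_k: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "centroids", np.asarray(self.centroids, dtype=float))
        object.__setattr__(self, "assignments", np.asarray(self.assignments, dtype=int))


def _widths(pts: np.ndarray, labels: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """Per-cluster radius: max member-to-own-centroid distance."""
    return np.array(
        [
            np.max(np.linalg.norm(pts[labels == i] - c, axis=1))
            if np.any(labels == i)
            else 0.0
            for i, c in enumerate(centroids)
        ]
    )


def _min_gap(pts: np.ndarray, labels: np.ndarray, k: int) -> float:
    """Minimum distance between members of different clusters."""
    gaps = []
    members = [pts[labels == i] for i in range(k)]
    for i in range(k):
        for j in range(i + 1, k):
            if members[i].size and members[j].size:
                gaps.append(float(cdist(members[i], members[j]).min()))
    return min(gaps) if gaps else np.inf


def find_clusters(pts: LorenzPoints, params: ClusterParams | None = None) -> ClusterResult:
    """Count well-separated clusters in a Lorenz plot.

    Fewer than 4 points trivially yield ``cluster_count = 1``.
    """
    p = params or ClusterParams()
    X = pts.points
    if not np.all(np.isfinite(X)):
        raise InvalidSignal("non-finite Lorenz coordinates")

    def trivial() -> ClusterResult:
        centroid = X.mean(axis=0, keepdims=True) if len(X) else np.zeros((1, 2))
        return ClusterResult(1, centroid, np.zeros(len(X), dtype=int), 1)

    if len(X) < 4:
        return trivial()

    k_hi = min(p.k_max, len(X) // max(p.min_cluster_size, 1))
    for k in range(k_hi, 1, -1):
        km = KMeans(n_clusters=k, n_init=p.n_restarts, random_state=p.seed)
        labels = km.fit_predict(X)
        C = km.cluster_centers_
        sizes = np.bincount(labels, minlength=k)
        if sizes.min() < p.min_cluster_size:
            continue
        if _widths(X, labels, C).max() > p.max_cluster_width:
            continue
        if _min_gap(X, labels, k) <= p.min_separation:
            continue
        return ClusterResult(k, C, labels, k)
    return trivial()


@dataclass(frozen=True)
class ClusterSummary:
    """Per-cluster diagnostics for reports and plots."""

    sizes: list[int] = field(default_factory=list)
    widths: list[float] = field(default_factory=list)
    centroids: list[tuple[float, float]] = field(default_factory=list)


def cluster_report(result: ClusterResult, pts: LorenzPoints) -> ClusterSummary:
    """Recompute per-cluster size, width and centroid from assignments."""
    X = pts.points
    if len(X) == 0:
        raise InvalidSignal("no points to report on")
    k = result.cluster_count
    w = _widths(X, result.assignments, result.centroids)
    sizes = np.bincount(result.assignments, minlength=k)
    return ClusterSummary(
        sizes=[int(s) for s in sizes],
        widths=[float(x) for x in w],
        centroids=[(float(a), float(b)) for a, b in result.centroids],
    )
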