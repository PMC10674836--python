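"""The two RR-interval irregularity features.

``count_rr`` counts the intervals that sit within +/-15 ms of the strip's
median interval and divides by the heart rate: a regular rhythm has many
near-median intervals (high values), a completely irregular one almost
none.  ``svd_ratio`` is the ratio of the two singular values of the raw
(uncentred) Lorenz-plot coordinate matrix: a regular rhythm collapses the
plot onto a single direction along the identity diagonal, driving the
second singular value toward zero and the ratio toward infinity, while an
irregular rhythm fills the plane isotropically and keeps the ratio small.

The SVD is deliberately computed on *uncentred* coordinates: only then does
a perfectly regular rhythm (all points at one spot far from the origin)
become rank-1 and make the ratio explode, matching the order-of-magnitude
separation between regular and fibrillating rhythms that motivates the
feature.  Mean-centring would instead send regular rhythms toward a ratio
of ~1 and destroy the contrast.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import InsufficientBeats, RRSeries

#: Half-width (seconds) of the near-median window for count_rr.  The
#: comparison is inclusive: boundary ties count as matches.
MEDIAN_TOLERANCE = 0.015

#: Sentinel returned instead of +inf for a rank-deficient Lorenz matrix so
#: that finite <= threshold comparisons stay well-defined.
SVD_RATIO_CAP = 1e6


@dataclass(frozen=True)
class LorenzPoints:
    """Lag-1 embedding (RR_n, RR_{n+1}) of an RR series, order preserved."""

    points: np.ndarray  # shape (n-1, 2)

    def __post_init__(self) -> None:
        p = np.asarray(self.points, dtype=float).reshape(-1, 2)
        object.__setattr__(self, "points", p)

    def __len__(self) -> int:
        return int(self.points.shape[0])


@dataclass(frozen=True)
class FeatureVector:
    """Per-strip irregularity features plus bookkeeping."""

    count_rr: float
    svd_ratio: float
    heart_rate: float
    n_intervals: int


def heart_rate(rr: RRSeries) -> float:
    """Mean heart rate over the strip, beats/minute: 60 / mean(RR)."""
    if rr.n_intervals < 1:
        raise InsufficientBeats("heart rate needs at least one interval")
    return 60.0 / float(np.mean(rr.intervals))


def count_rr(rr: RRSeries, tolerance: float = MEDIAN_TOLERANCE) -> float:
    """Number of intervals within ``tolerance`` of the median interval,
    divided by the heart rate.

    Uses the even-length median convention (mean of the two central
    values).  Insensitive to interval order; NOT scale-invariant, because
    the 15 ms window is absolute.
    """
    if rr.n_intervals < 5:
        raise InsufficientBeats(
            f"insufficient intervals: {rr.n_intervals}, need >= 5"
        )
    med = float(np.median(rr.intervals))
    matches = int(np.sum(np.abs(rr.intervals - med) <= tolerance))
    return matches / heart_rate(rr)


def lorenz(rr: RRSeries) -> LorenzPoints:
    """Lorenz (Poincare) embedding: point i = (RR_i, RR_{i+1})."""
    if rr.n_intervals < 2:
        raise InsufficientBeats("Lorenz plot needs at least two intervals")
    iv = rr.intervals
    return LorenzPoints(np.column_stack([iv[:-1], iv[1:]]))


def svd_ratio(pts: LorenzPoints, cap: float = SVD_RATIO_CAP) -> float:
    """Ratio s1/s2 of the singular values of the raw Lorenz matrix.

    Always >= 1 when finite; scale-invariant; capped at ``cap`` when the
    matrix is (numerically) rank-1, i.e. s2 < 1e-12 * s1.
    """
    if len(pts) < 3:
        raise InsufficientBeats(f"insufficient points: {len(pts)}, need >= 3")
    s = np.linalg.svd(pts.points, compute_uv=False)
    s1, s2 = float(s[0]), float(s[1])
    if s2 < 1e-12 * s1:
        return cap
    return min(s1 / s2, cap)


def extract_features(rr: RRSeries) -> FeatureVector:
    """Both irregularity features for one strip."""
    return FeatureVector(
        count_rr=count_rr(rr),
        svd_ratio=svd_ratio(lorenz(rr)),
        heart_rate=heart_rate(rr),
        n_intervals=rr.n_intervals,
    )
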