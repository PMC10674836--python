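"""The two-step AF decision rule.

Step 1 — irregularity: a strip is irregular when BOTH features fall at or
below their cutoffs (count_rr <= count_rr_max AND svd_ratio <=
svd_ratio_max).  Step 2 — regularity veto: an irregular strip is called AF
only when the Lorenz plot shows no regular cluster structure
(cluster_count == 1); two or more accepted clusters mean the irregularity
has a repeating pattern (premature beats, grouped beating) and the AF call
is withdrawn.

The rule is all-inclusive: every strip with at least five intervals gets a
definite AF / NOT_AF verdict — there is no "inconclusive" outcome and no
heart-rate or quality exclusion window.  Strips too short to classify
raise an error instead of guessing.

Default cutoffs are the published validated rule (count RR <= 0.158, SVD
ratio <= 13.31, cluster count == 1).  An alternative count RR cutoff of
0.146 appears in the same source's threshold-search stage; both are plain
config values here, 0.158 being the default.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

from .clustering import ClusterParams, find_clusters
from .core import InsufficientBeats, RRSeries
from .features import FeatureVector, extract_features, lorenz
from .rpeak import PeakConfig, detect_r_peaks, rr_from_peaks
from .simulate import ECGRecord

#: Published validated cutoffs.
DEFAULT_COUNT_RR_MAX = 0.158
DEFAULT_SVD_RATIO_MAX = 13.31
#: Alternative count RR cutoff from the threshold-search stage.
ALT_COUNT_RR_MAX = 0.146


class Verdict(str, enum.Enum):
    AF = "AF"
    NOT_AF = "NOT_AF"


@dataclass(frozen=True)
class DecisionThresholds:
    count_rr_max: float = DEFAULT_COUNT_RR_MAX
    svd_ratio_max: float = DEFAULT_SVD_RATIO_MAX
    required_cluster_count: int = 1
    cluster_params: ClusterParams = field(default_factory=ClusterParams)

    def __post_init__(self) -> None:
        if min(self.count_rr_max, self.svd_ratio_max) <= 0:
            raise ValueError("thresholds must be positive")
        if self.required_cluster_count < 1:
            raise ValueError("required_cluster_count must be >= 1")


@dataclass(frozen=True)
class Decision:
    """Full rule evaluation for one strip.

    ``cluster_count`` is 0 when step 1 already rejected the strip and
    clustering was skipped (0 = not evaluated, never a valid count).
    """

    verdict: Verdict
    step1_irregular: bool
    features: FeatureVector
    cluster_count: int
    trace: str


def apply_rule(
    features: FeatureVector,
    thr: DecisionThresholds,
    cluster_count: int | None = None,
) -> Decision:
    """Evaluate the decision rule on precomputed features.

    ``cluster_count`` may be precomputed; when ``None`` and step 1 passes,
    the caller must supply it (this pure function never runs clustering).
    Threshold comparisons are inclusive (<=).
    """
    c_ok = features.count_rr <= thr.count_rr_max
    s_ok = features.svd_ratio <= thr.svd_ratio_max
    step1 = bool(c_ok and s_ok)
    lines = [
        f"count_rr {features.count_rr:.4f} <= {thr.count_rr_max}: {c_ok}",
        f"svd_ratio {features.svd_ratio:.4f} <= {thr.svd_ratio_max}: {s_ok}",
        f"step 1 irregular: {step1}",
    ]
    if not step1:
        lines.append("clustering skipped; verdict NOT_AF")
        return Decision(Verdict.NOT_AF, False, features, 0, "\n".join(lines))
    if cluster_count is None:
        raise ValueError("cluster_count required when step 1 passes")
    af = cluster_count == thr.required_cluster_count
    lines.append(
        f"cluster_count {cluster_count} == {thr.required_cluster_count}: {af}"
    )
    lines.append(f"verdict {'AF' if af else 'NOT_AF (regularity within irregularity)'}")
    return Decision(
        Verdict.AF if af else Verdict.NOT_AF, True, features, cluster_count,
        "\n".join(lines),
    )


def classify_rr(rr: RRSeries, thr: DecisionThresholds | None = None) -> Decision:
    """Two-step rule on an RR series (clustering run only when needed)."""
    thr = thr or DecisionThresholds()
    if rr.n_intervals < 5:
        raise InsufficientBeats(
            f"insufficient beats: {rr.n_intervals} intervals, need >= 5"
        )
    feats = extract_features(rr)
    prelim = apply_rule(feats, thr, cluster_count=0) if not _step1(feats, thr) else None
    if prelim is not None:
        return prelim
    result = find_clusters(lorenz(rr), thr.cluster_params)
    return apply_rule(feats, thr, cluster_count=result.cluster_count)


def _step1(f: FeatureVector, thr: DecisionThresholds) -> bool:
    return f.count_rr <= thr.count_rr_max and f.svd_ratio <= thr.svd_ratio_max


def classify_ecg(
    record: ECGRecord,
    thr: DecisionThresholds | None = None,
    peak_config: PeakConfig | None = None,
) -> Decision:
    """End-to-end: detect R peaks, form RR intervals, apply the rule."""
    peaks = detect_r_peaks(record.samples, record.sampling_rate, peak_config)
    rr = rr_from_peaks(peaks, duration=record.duration)
    return classify_rr(rr, thr)
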