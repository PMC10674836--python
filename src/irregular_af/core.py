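"""Core containers and exceptions shared across the pipeline.

Units are fixed package-wide: times in seconds, voltages in millivolts,
sample indices 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class IrregularAFError(Exception):
    """Base class for all package errors."""


class InsufficientBeats(IrregularAFError):
    """Too few detected beats / RR intervals to compute a statistic."""


class InsufficientDuration(IrregularAFError):
    """Requested strip too short to hold the minimum number of intervals."""


class InvalidSignal(IrregularAFError):
    """Non-finite samples, non-monotone time axis, or malformed input."""


class ValidationError(IrregularAFError):
    """Malformed file contents or configuration."""


@dataclass(frozen=True)
class RRSeries:
    """Ordered RR intervals (seconds) extracted from one ECG strip.

    ``n_beats`` is always ``len(intervals) + 1``: n beats bound n-1
    intervals.  ``source_duration`` is the duration of the strip the
    intervals came from, when known.
    """

    intervals: np.ndarray
    source_duration: float | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.intervals, dtype=float)
        if arr.ndim != 1:
            raise ValidationError("intervals must be one-dimensional")
        if arr.size and (not np.all(np.isfinite(arr)) or np.any(arr <= 0)):
            raise ValidationError("RR intervals must be finite and positive")
        object.__setattr__(self, "intervals", arr)

    @property
    def n_intervals(self) -> int:
        return int(self.intervals.size)

    @property
    def n_beats(self) -> int:
        return int(self.intervals.size) + 1

    def __len__(self) -> int:
        return self.n_intervals

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RRSeries):
            return NotImplemented
        return (
            np.array_equal(self.intervals, other.intervals)
            and self.source_duration == other.source_duration
        )

    def __hash__(self) -> int:  # frozen dataclass with array field
        return hash((self.intervals.tobytes(), self.source_duration))


@dataclass(frozen=True)
class PeakTimes:
    """Detected R-peak times (seconds, strictly increasing) with a
    per-peak confidence in [0, 1]."""

    times: np.ndarray
    confidence: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValidationError("peak times must be strictly increasing")
        conf = (
            np.ones_like(t)
            if self.confidence is None
            else np.asarray(self.confidence, dtype=float)
        )
        if conf.shape != t.shape:
            raise ValidationError("confidence must match times in shape")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "confidence", conf)

    def __len__(self) -> int:
        return int(self.times.size)
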