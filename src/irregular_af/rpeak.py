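"""R-peak detection via wavelet enhancement and multi-pass peak finding.

The QRS complex concentrates its energy around 10-40 Hz.  An undecimated
(maximal-overlap) discrete wavelet transform decomposes the signal into
octave bands; only the detail levels whose passband overlaps the QRS band
are kept, everything else (baseline wander, T waves, high-frequency noise)
is zeroed, and the squared reconstruction serves as a nonnegative QRS
envelope.  Peaks are then found in three passes:

1. envelope peaks above an adaptive threshold (a fraction of the rolling
   envelope maximum) with a refractory spacing;
2. any inter-peak gap longer than 1.5x the running median RR is re-searched
   with the threshold halved, rescuing low-amplitude beats;
3. each detection is snapped to the extremum of the raw signal (polarity
   aware, via the absolute deviation from the local baseline) within a
   +/-60 ms window.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pywt
from scipy.ndimage import maximum_filter1d
from scipy.signal import find_peaks

from .core import InsufficientBeats, InvalidSignal, PeakTimes, RRSeries

QRS_BAND = (10.0, 40.0)  # Hz


@dataclass(frozen=True)
class PeakConfig:
    """Detector tuning knobs (all exposed; defaults suit 30 s strips)."""

    wavelet: str = "sym4"
    threshold_fraction: float = 0.25
    rolling_window: float = 2.0  # s, for the adaptive threshold
    refractory: float = 0.25  # s, 240 bpm guard
    gap_factor: float = 1.5
    snap_window: float = 0.06  # s, pass-3 half-width
    noise_floor: float = 0.05  # fraction of global envelope max


def _qrs_levels(sampling_rate: float, max_level: int) -> list[int]:
    """Detail levels whose dyadic passband [fs/2^(j+1), fs/2^j] overlaps
    the QRS band."""
    levels = []
    for j in range(1, max_level + 1):
        lo, hi = sampling_rate / 2 ** (j + 1), sampling_rate / 2**j
        if hi > QRS_BAND[0] and lo < QRS_BAND[1]:
            levels.append(j)
    return levels


def enhance_qrs(
    samples: np.ndarray, sampling_rate: float, config: PeakConfig | None = None
) -> np.ndarray:
    """Squared band-limited wavelet reconstruction of the QRS content.

    Same length as the input; zero wherever the signal has no energy in
    the QRS band.
    """
    cfg = config or PeakConfig()
    x = np.asarray(samples, dtype=float)
    if not np.all(np.isfinite(x)):
        raise InvalidSignal("invalid signal: non-finite samples")
    if sampling_rate < 128:
        raise InvalidSignal("sampling_rate must be >= 128 Hz")
    if x.size < 2 * sampling_rate:
        raise InvalidSignal("too short: need >= 2 s of signal")

    # deepest level whose band still reaches down toward the QRS band
    max_level = max(1, int(np.floor(np.log2(sampling_rate / QRS_BAND[0]))) - 1)
    levels = _qrs_levels(sampling_rate, max_level)
    depth = max(levels)

    # the undecimated transform needs a length divisible by 2^depth
    block = 2**depth
    pad = (-x.size) % block
    xp = np.pad(x, (0, pad), mode="reflect") if pad else x

    coeffs = pywt.swt(xp, cfg.wavelet, level=depth, norm=True, trim_approx=True)
    # coeffs = [approx, detail_depth, ..., detail_1]
    kept = [np.zeros_like(coeffs[0])]
    for j in range(depth, 0, -1):
        d = coeffs[depth - j + 1]
        kept.append(d if j in levels else np.zeros_like(d))
    rec = pywt.iswt(kept, cfg.wavelet, norm=True)
    rec = rec[: x.size]
    return rec**2


def detect_r_peaks(
    samples: np.ndarray, sampling_rate: float, config: PeakConfig | None = None
) -> PeakTimes:
    """Three-pass R-peak detection; returns an empty result (not an error)
    when the strip has no QRS energy."""
    cfg = config or PeakConfig()
    x = np.asarray(samples, dtype=float)
    env = enhance_qrs(x, sampling_rate, cfg)

    gmax = float(env.max())
    if gmax <= 0:
        return PeakTimes(np.array([]), np.array([]))

    win = max(3, int(cfg.rolling_window * sampling_rate))
    rolling = maximum_filter1d(env, size=win, mode="nearest")
    thr = np.maximum(cfg.threshold_fraction * rolling, cfg.noise_floor * gmax)
    refr = max(1, int(cfg.refractory * sampling_rate))

    # Pass 1: adaptive-threshold peaks with refractory spacing.
    idx, _ = find_peaks(env, height=thr, distance=refr)
    if idx.size == 0:
        return PeakTimes(np.array([]), np.array([]))

    # Pass 2: rescue low-amplitude beats inside anomalously long gaps.
    if idx.size >= 3:
        median_rr = float(np.median(np.diff(idx)))
        rescued = []
        bounds = np.concatenate([[0], idx, [env.size - 1]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            if b - a > cfg.gap_factor * median_rr:
                seg = env[a:b]
                sub, _ = find_peaks(seg, height=thr[a:b] / 2.0, distance=refr)
                for s in sub:
                    g = a + s
                    if np.all(np.abs(g - idx) >= refr):
                        rescued.append(g)
        if rescued:
            idx = np.sort(np.concatenate([idx, np.array(rescued, dtype=idx.dtype)]))

    # Pass 3: snap to the raw-signal extremum (polarity aware).
    half = int(cfg.snap_window * sampling_rate)
    snapped = []
    for i in idx:
        lo, hi = max(0, i - half), min(x.size, i + half + 1)
        seg = x[lo:hi]
        baseline = np.median(seg)
        snapped.append(lo + int(np.argmax(np.abs(seg - baseline))))
    snapped = np.array(sorted(set(snapped)))

    # enforce refractory after snapping, keeping the stronger envelope peak
    keep: list[int] = []
    for i in snapped:
        if keep and i - keep[-1] < refr:
            if env[i] > env[keep[-1]]:
                keep[-1] = int(i)
        else:
            keep.append(int(i))
    final = np.array(keep)

    conf = np.clip(env[final] / rolling[final], 0.0, 1.0)
    return PeakTimes(final / sampling_rate, conf)


def rr_from_peaks(peaks: PeakTimes, duration: float | None = None) -> RRSeries:
    """Successive differences of peak times.

    Requires at least 6 peaks (5 intervals) — the minimum the downstream
    irregularity statistics need; with fewer the strip cannot be classified
    and the caller should record a longer strip.
    """
    if len(peaks) < 6:
        raise InsufficientBeats(
            f"insufficient beats: {len(peaks)} peaks, need >= 6"
        )
    return RRSeries(np.diff(peaks.times), source_duration=duration)
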