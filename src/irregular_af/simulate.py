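"""Synthetic rhythm and single-lead ECG generation.

Each rhythm class reproduces the RR-interval phenomenology that drives the
detector, not realistic waveform morphology:

* ``SINUS`` — near-constant intervals with small Gaussian jitter and a slow
  respiratory sinusoidal modulation, so the rhythm is regular but not
  degenerate.
* ``AF`` — intervals drawn i.i.d. from a uniform distribution, the simplest
  model of a completely irregular ("irregularly irregular") ventricular
  rhythm with no lag structure.
* ``PAC`` / ``PVC`` — a sinus base interrupted every k-th beat by a premature
  beat: a short coupling interval followed by a long compensatory pause.
  The three interval types form the discrete Lorenz-plot clusters the
  second detection stage looks for.
* ``AVB`` — Wenckebach-style grouped beating: runs of conducted beats, then
  a dropped beat producing an interval about twice the base.
* ``SSS`` — bradycardic base rhythm with occasional sinus pauses >= 2 s.

ECG waveforms are sums of Gaussian bumps (P, Q, R, S, T) centred at each
beat time; PVC beats get a wide negative-dominant QRS with no P wave, and
AF records carry no P waves at all.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np

from .core import InsufficientDuration, RRSeries, ValidationError

#: Physiological RR bounds (seconds) applied to all classes except
#: deliberate SSS pauses: 0.24 s = 250 bpm, 3.0 s extreme pause.
RR_MIN = 0.24
RR_MAX = 3.0


class RhythmLabel(str, enum.Enum):
    """Rhythm classes the generator can produce."""

    SINUS = "sinus"
    AF = "af"
    PAC = "pac"
    PVC = "pvc"
    AVB = "avb"
    SSS = "sss"

    @classmethod
    def coerce(cls, value: "RhythmLabel | str") -> "RhythmLabel":
        if isinstance(value, cls):
            return value
        return cls(str(value).lower())


@dataclass(frozen=True)
class RhythmParams:
    """Tunable rhythm-generation parameters.

    All times in seconds.  ``coupling_fraction`` and ``pause_fraction`` are
    multiples of ``mean_rr`` for the premature beat's coupling interval and
    the post-ectopic pause; ``ectopy_period`` makes every k-th beat
    premature (set ``ectopy_prob`` instead for random ectopy).
    ``wenckebach_ratio`` is (P waves : conducted QRS), e.g. (4, 3).
    """

    mean_rr: float = 1.0
    rr_jitter_sd: float = 0.02
    resp_mod_amplitude: float = 0.03
    resp_mod_period: float = 4.0
    af_low: float = 0.4
    af_high: float = 1.2
    coupling_fraction: float = 0.65
    pause_fraction: float = 1.35
    ectopy_period: int | None = 3
    ectopy_prob: float | None = None
    wenckebach_ratio: tuple[int, int] = (4, 3)
    pause_prob: float = 0.08
    pause_range: tuple[float, float] = (2.0, 2.8)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mean_rr <= 0:
            raise ValidationError("mean_rr must be positive")
        if not 0 < self.af_low < self.af_high:
            raise ValidationError("need 0 < af_low < af_high")
        if not 0 < self.coupling_fraction < 1 < self.pause_fraction:
            raise ValidationError(
                "need 0 < coupling_fraction < 1 < pause_fraction"
            )
        if self.rr_jitter_sd < 0:
            raise ValidationError("rr_jitter_sd must be >= 0")


#: Per-class defaults chosen to reproduce the qualitative Lorenz-plot
#: geometry of each rhythm and the published ordering of the class medians
#: for both irregularity features.
CLASS_DEFAULTS: dict[RhythmLabel, RhythmParams] = {
    RhythmLabel.SINUS: RhythmParams(mean_rr=1.0),
    RhythmLabel.AF: RhythmParams(af_low=0.4, af_high=1.2),
    RhythmLabel.PAC: RhythmParams(
        mean_rr=1.0, coupling_fraction=0.60, pause_fraction=1.40, ectopy_period=3
    ),
    # Typical ventricular ectopy: ~0.4 s coupling interval with a full
    # compensatory pause (coupling + pause = 2 cycles), a few PVCs per strip.
    RhythmLabel.PVC: RhythmParams(
        mean_rr=0.95, rr_jitter_sd=0.015,
        coupling_fraction=0.42, pause_fraction=1.58, ectopy_period=12
    ),
    RhythmLabel.AVB: RhythmParams(
        mean_rr=0.9, rr_jitter_sd=0.01, resp_mod_amplitude=0.015,
        wenckebach_ratio=(4, 3),
    ),
    RhythmLabel.SSS: RhythmParams(
        mean_rr=1.3, rr_jitter_sd=0.015, resp_mod_amplitude=0.015, pause_prob=0.08
    ),
}


def default_params(label: RhythmLabel | str, seed: int | None = None) -> RhythmParams:
    """Per-class default :class:`RhythmParams`, optionally re-seeded."""
    p = CLASS_DEFAULTS[RhythmLabel.coerce(label)]
    return p if seed is None else replace(p, seed=seed)


def simulate_rr(
    label: RhythmLabel | str,
    params: RhythmParams | None = None,
    duration: float = 30.0,
) -> tuple[RRSeries, list[str]]:
    """Generate one labelled RR series of roughly ``duration`` seconds.

    Returns the series and a per-interval type annotation (``"base"``,
    ``"af"``, ``"coupling"``, ``"pause"``, ``"dropped"``).  The last
    interval that would cross ``duration`` is dropped, not truncated, so
    interval statistics carry no artificial short interval.
    """
    label = RhythmLabel.coerce(label)
    p = params if params is not None else default_params(label)
    if duration < 10.0:
        raise InsufficientDuration("duration must be >= 10 s")
    rng = np.random.default_rng(p.seed)

    intervals: list[float] = []
    types: list[str] = []
    t = 0.0

    def push(rr: float, kind: str, clip: bool = True) -> bool:
        nonlocal t
        if clip:
            rr = float(np.clip(rr, RR_MIN, RR_MAX))
        if t + rr > duration:
            return False
        intervals.append(rr)
        types.append(kind)
        t += rr
        return True

    def base_rr() -> float:
        mod = p.resp_mod_amplitude * np.sin(2 * np.pi * t / p.resp_mod_period)
        return p.mean_rr + mod + rng.normal(0.0, p.rr_jitter_sd)

    if label is RhythmLabel.AF:
        while push(rng.uniform(p.af_low, p.af_high), "af"):
            pass
    elif label is RhythmLabel.SINUS:
        while push(base_rr(), "base"):
            pass
    elif label in (RhythmLabel.PAC, RhythmLabel.PVC):
        if p.ectopy_prob is not None:
            going = True
            while going:
                if rng.random() < p.ectopy_prob:
                    jit = rng.normal(0.0, p.rr_jitter_sd, 2)
                    going = push(p.coupling_fraction * p.mean_rr + jit[0], "coupling")
                    if going:
                        going = push(p.pause_fraction * p.mean_rr + jit[1], "pause")
                else:
                    going = push(base_rr(), "base")
        else:
            # Every k-th beat premature: the steady-state cycle over k beats
            # is (k-2) base intervals, the coupling interval into the
            # ectopic, and the compensatory pause out of it (k = 3 is true
            # trigeminy: base, coupling, pause).
            period = p.ectopy_period or 3
            if period < 2:
                raise ValidationError("ectopy_period must be >= 2")
            i = 0
            while True:
                r = i % period
                if r == period - 2:
                    ok = push(
                        p.coupling_fraction * p.mean_rr
                        + rng.normal(0.0, p.rr_jitter_sd),
                        "coupling",
                    )
                elif r == period - 1:
                    ok = push(
                        p.pause_fraction * p.mean_rr
                        + rng.normal(0.0, p.rr_jitter_sd),
                        "pause",
                    )
                else:
                    ok = push(base_rr(), "base")
                if not ok:
                    break
                i += 1
    elif label is RhythmLabel.AVB:
        n_p, n_qrs = p.wenckebach_ratio
        if not (n_p > n_qrs >= 2):
            raise ValidationError("wenckebach_ratio must be (P, QRS) with P > QRS >= 2")
        # n_qrs conducted beats per cycle: n_qrs - 1 base intervals, then
        # the dropped beat spans ~2x the base interval.
        going = True
        while going:
            for _ in range(n_qrs - 1):
                going = push(base_rr(), "base")
                if not going:
                    break
            if going:
                going = push(2.0 * p.mean_rr + rng.normal(0.0, p.rr_jitter_sd), "dropped")
    elif label is RhythmLabel.SSS:
        while True:
            if rng.random() < p.pause_prob:
                ok = push(rng.uniform(*p.pause_range), "pause", clip=False)
            else:
                ok = push(base_rr(), "base")
            if not ok:
                break
    else:  # pragma: no cover - exhaustive enum
        raise ValidationError(f"unknown label {label}")

    if len(intervals) < 5:
        raise InsufficientDuration(
            f"insufficient duration: only {len(intervals)} intervals fit in {duration} s"
        )
    return RRSeries(np.array(intervals), source_duration=duration), types


# ---------------------------------------------------------------------------
# Waveform synthesis


@dataclass(frozen=True)
class ECGRecord:
    """A sampled single-lead strip with ground-truth beat annotations."""

    samples: np.ndarray
    sampling_rate: float
    duration: float
    true_r_times: np.ndarray
    label: RhythmLabel
    record_id: str = ""
    rr: RRSeries | None = None
    interval_types: tuple[str, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        s = np.asarray(self.samples, dtype=float)
        r = np.asarray(self.true_r_times, dtype=float)
        if s.size != round(self.duration * self.sampling_rate):
            raise ValidationError("sample count must equal duration * sampling_rate")
        if r.size > 1 and np.any(np.diff(r) <= 0):
            raise ValidationError("true_r_times must be strictly increasing")
        if r.size and (r[0] < 0 or r[-1] > self.duration):
            raise ValidationError("true_r_times must lie within [0, duration]")
        object.__setattr__(self, "samples", s)
        object.__setattr__(self, "true_r_times", r)


# (offset s, amplitude mV, width s) Gaussian bumps relative to the R time.
NORMAL_TEMPLATE = (
    ("P", -0.20, 0.12, 0.025),
    ("Q", -0.03, -0.08, 0.010),
    ("R", 0.00, 1.10, 0.012),
    ("S", 0.03, -0.18, 0.012),
    ("T", 0.25, 0.28, 0.050),
)
# Wide negative-dominant biphasic QRS (slurred RS, ~120 ms), discordant T,
# no P: a ventricular ectopic as seen in lead I.
PVC_TEMPLATE = (
    ("R", 0.00, -1.30, 0.016),
    ("S", 0.05, 0.60, 0.022),
    ("T", 0.32, 0.50, 0.070),
)


def _template_span(template) -> float:
    """Width of the QRS core of a template.  P and T bumps are allowed to
    merge with neighbouring beats (they do physiologically at fast rates);
    only QRS overlap makes a rhythm unrenderable."""
    return max(abs(off) + 4 * w for name, off, _, w in template if name in "QRS")


def simulate_ecg(
    rr: RRSeries,
    sampling_rate: float = 512.0,
    *,
    label: RhythmLabel | str = RhythmLabel.SINUS,
    interval_types: list[str] | None = None,
    noise_sd: float = 0.0,
    baseline_wander_amplitude: float = 0.0,
    baseline_wander_freq: float = 0.3,
    amplitude_scale: float | np.ndarray = 1.0,
    first_r_time: float = 0.35,
    seed: int = 0,
    record_id: str = "",
) -> ECGRecord:
    """Render an RR series as a sampled voltage trace.

    One beat template is centred at each cumulative beat time.  With a
    ``label`` of PVC, beats terminating a coupling interval get the wide
    ventricular template; with AF, P waves are omitted everywhere.  Noise
    and baseline wander are additive and never move ``true_r_times``.
    """
    label = RhythmLabel.coerce(label)
    if sampling_rate < 128:
        raise ValidationError("sampling_rate must be >= 128 Hz")
    shortest = float(np.min(rr.intervals))
    if _template_span(NORMAL_TEMPLATE) >= shortest:
        raise ValidationError(
            f"morphology overlap: template span >= shortest RR ({shortest:.3f} s)"
        )
    duration = (
        rr.source_duration
        if rr.source_duration is not None
        else first_r_time + float(np.sum(rr.intervals)) + 1.0
    )
    beat_times = first_r_time + np.concatenate([[0.0], np.cumsum(rr.intervals)])
    # Beats whose R peak would sit against the strip edge are dropped (and
    # the ground-truth RR trimmed with them) so every rendered R is whole.
    keep = beat_times <= duration - 0.1
    beat_times = beat_times[keep]
    if beat_times.size < 2:
        raise ValidationError("record too short to hold two beats")
    intervals_eff = rr.intervals[: beat_times.size - 1]
    rr_eff = RRSeries(intervals_eff, source_duration=duration)

    n = round(duration * sampling_rate)
    tgrid = np.arange(n) / sampling_rate
    x = np.zeros(n)

    types = list(interval_types or [])[: beat_times.size - 1]
    amp = np.asarray(amplitude_scale, dtype=float)
    if amp.ndim == 1 and amp.size == keep.size:
        amp = amp[keep]
    scales = np.broadcast_to(amp, beat_times.shape)
    for i, bt in enumerate(beat_times):
        is_pvc_beat = (
            label is RhythmLabel.PVC and i >= 1 and i - 1 < len(types)
            and types[i - 1] == "coupling"
        )
        template = PVC_TEMPLATE if is_pvc_beat else NORMAL_TEMPLATE
        for name, off, amp, w in template:
            if name == "P" and label is RhythmLabel.AF:
                continue
            centre = bt + off
            lo = max(0, int((centre - 5 * w) * sampling_rate))
            hi = min(n, int((centre + 5 * w) * sampling_rate) + 1)
            if lo >= hi:
                continue
            seg = tgrid[lo:hi]
            x[lo:hi] += scales[i] * amp * np.exp(-0.5 * ((seg - centre) / w) ** 2)

    rng = np.random.default_rng(seed)
    if noise_sd > 0:
        x = x + rng.normal(0.0, noise_sd, n)
    if baseline_wander_amplitude > 0:
        x = x + baseline_wander_amplitude * np.sin(
            2 * np.pi * baseline_wander_freq * tgrid
        )

    return ECGRecord(
        samples=x,
        sampling_rate=sampling_rate,
        duration=duration,
        true_r_times=beat_times,
        label=label,
        record_id=record_id,
        rr=rr_eff,
        interval_types=tuple(types),
    )


def simulate_record(
    label: RhythmLabel | str,
    seed: int,
    *,
    duration: float = 30.0,
    sampling_rate: float = 512.0,
    noise_sd: float = 0.02,
    record_id: str = "",
) -> ECGRecord:
    """Convenience: one labelled ECG record with class-default parameters."""
    label = RhythmLabel.coerce(label)
    rr, types = simulate_rr(label, default_params(label, seed=seed), duration)
    return simulate_ecg(
        rr,
        sampling_rate,
        label=label,
        interval_types=types,
        noise_sd=noise_sd,
        seed=seed + 1,
        record_id=record_id,
    )


def _child_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(c.generate_state(1)[0] % 2**31) for c in ss.spawn(n)]


def simulate_cohort(
    n_per_class: int,
    seed: int,
    *,
    duration: float = 30.0,
    sampling_rate: float = 512.0,
    noise_sd: float = 0.02,
    classes: tuple[RhythmLabel, ...] = tuple(RhythmLabel),
) -> list[ECGRecord]:
    """Class-balanced labelled cohort; per-record seeds are spawned
    deterministically from the cohort seed, so the same (n, seed) always
    reproduces the same records."""
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    seeds = _child_seeds(seed, n_per_class * len(classes))
    records = []
    k = 0
    for label in classes:
        for i in range(n_per_class):
            records.append(
                simulate_record(
                    label,
                    seeds[k],
                    duration=duration,
                    sampling_rate=sampling_rate,
                    noise_sd=noise_sd,
                    record_id=f"{label.value}-{i:03d}",
                )
            )
            k += 1
    return records


def simulate_rr_cohort(
    n_per_class: int,
    seed: int,
    *,
    duration: float = 30.0,
    classes: tuple[RhythmLabel, ...] = tuple(RhythmLabel),
) -> list[tuple[str, RhythmLabel, RRSeries]]:
    """RR-level cohort (no waveform synthesis) for feature-space studies.

    Uses the same per-class defaults and seed-spawning scheme as
    :func:`simulate_cohort`.
    """
    if n_per_class < 1:
        raise ValidationError("n_per_class must be >= 1")
    seeds = _child_seeds(seed, n_per_class * len(classes))
    out = []
    k = 0
    for label in classes:
        for i in range(n_per_class):
            rr, _ = simulate_rr(label, default_params(label, seed=seeds[k]), duration)
            out.append((f"{label.value}-{i:03d}", label, rr))
            k += 1
    return out
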