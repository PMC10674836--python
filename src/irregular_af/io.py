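"""File formats: RR / ECG / label CSVs, thresholds YAML, decision JSON.

Conventions enforced everywhere: times in seconds, voltages in millivolts,
0-based sample indexing.  CSV is the interchange format — the upstream
data source is digitised strips, for which no community binary standard
exists.
"""

from __future__ import annotations

import dataclasses
import difflib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .classify import Decision, DecisionThresholds
from .clustering import ClusterParams
from .core import RRSeries, ValidationError
from .simulate import ECGRecord, RhythmLabel


@dataclass
class Dataset:
    """A collection of RR series keyed by unique record id, with optional
    gold-standard labels and an optional external-classifier verdict
    (which may be "inconclusive")."""

    rr: dict[str, RRSeries] = field(default_factory=dict)
    labels: dict[str, str] = field(default_factory=dict)
    external: dict[str, str] = field(default_factory=dict)

    @property
    def record_ids(self) -> list[str]:
        return list(self.rr)


RR_HEADER = ["record_id", "idx", "rr_seconds"]


def write_rr_csv(ds: Dataset, path: str | Path) -> None:
    rows = []
    for rid, rr in ds.rr.items():
        for i, v in enumerate(rr.intervals):
            rows.append((rid, i, v))
    pd.DataFrame(rows, columns=RR_HEADER).to_csv(path, index=False)


def read_rr_csv(path: str | Path) -> Dataset:
    df = pd.read_csv(path)
    if list(df.columns) != RR_HEADER:
        raise ValidationError(
            f"missing or wrong header: expected {RR_HEADER}, got {list(df.columns)}"
        )
    if df.empty:
        raise ValidationError("no records in RR CSV")
    bad = df.index[df["rr_seconds"] <= 0]
    if len(bad):
        # +2: header line plus 0-based index
        raise ValidationError(
            f"non-positive rr_seconds at file row {int(bad[0]) + 2}"
        )
    ds = Dataset()
    for rid, grp in df.groupby("record_id", sort=False):
        grp = grp.sort_values("idx")
        ds.rr[str(rid)] = RRSeries(grp["rr_seconds"].to_numpy(dtype=float))
    return ds


def write_ecg_csv(record: ECGRecord, path: str | Path) -> None:
    t = np.arange(record.samples.size) / record.sampling_rate
    pd.DataFrame({"t_seconds": t, "mv": record.samples}).to_csv(path, index=False)


def read_ecg_csv(
    path: str | Path,
    sampling_rate: float | None = None,
    label: RhythmLabel | str = RhythmLabel.SINUS,
) -> ECGRecord:
    df = pd.read_csv(path)
    if list(df.columns)[:2] != ["t_seconds", "mv"]:
        raise ValidationError("ECG CSV must have columns t_seconds, mv")
    t = df["t_seconds"].to_numpy(dtype=float)
    x = df["mv"].to_numpy(dtype=float)
    if t.size < 2:
        raise ValidationError("ECG CSV too short")
    dt = np.diff(t)
    if np.any(dt <= 0):
        raise ValidationError("non-monotone time column")
    if np.max(np.abs(dt - dt[0])) > 1e-6:
        raise ValidationError("time gaps: sampling must be uniform")
    fs = sampling_rate if sampling_rate is not None else 1.0 / dt[0]
    return ECGRecord(
        samples=x,
        sampling_rate=fs,
        duration=x.size / fs,
        true_r_times=np.array([]),
        label=RhythmLabel.coerce(label),
        record_id=Path(path).stem,
    )


def read_labels_csv(path: str | Path) -> Dataset:
    """labels CSV: ``record_id, label[, aw_verdict]``."""
    df = pd.read_csv(path)
    if list(df.columns)[:2] != ["record_id", "label"]:
        raise ValidationError("labels CSV must start with record_id, label")
    ds = Dataset()
    ds.labels = {str(r): str(l) for r, l in zip(df["record_id"], df["label"])}
    if "aw_verdict" in df.columns:
        ds.external = {
            str(r): str(v) for r, v in zip(df["record_id"], df["aw_verdict"])
        }
    return ds


# ---------------------------------------------------------------------------
# Config

_THRESHOLD_KEYS = {"count_rr_max", "svd_ratio_max", "required_cluster_count"}
_CLUSTER_KEYS = {
    f.name for f in dataclasses.fields(ClusterParams)
}


def read_config(path: str | Path) -> DecisionThresholds:
    """YAML config with any subset of threshold / cluster keys; unknown
    keys are rejected with a closest-match suggestion."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError("config must be a YAML mapping")
    known = _THRESHOLD_KEYS | _CLUSTER_KEYS
    thr_kwargs: dict = {}
    cl_kwargs: dict = {}
    for key, value in raw.items():
        if key in _THRESHOLD_KEYS:
            thr_kwargs[key] = value
        elif key in _CLUSTER_KEYS:
            cl_kwargs[key] = value
        else:
            hint = difflib.get_close_matches(key, sorted(known), n=1)
            suffix = f"; did you mean {hint[0]!r}?" if hint else ""
            raise ValidationError(f"unknown config key {key!r}{suffix}")
    return DecisionThresholds(cluster_params=ClusterParams(**cl_kwargs), **thr_kwargs)


def write_config(thr: DecisionThresholds, path: str | Path) -> None:
    data = {
        "count_rr_max": thr.count_rr_max,
        "svd_ratio_max": thr.svd_ratio_max,
        "required_cluster_count": thr.required_cluster_count,
        **dataclasses.asdict(thr.cluster_params),
    }
    Path(path).write_text(yaml.safe_dump(data, sort_keys=False))


def decision_to_dict(decision: Decision, record_id: str = "") -> dict:
    return {
        "record_id": record_id,
        "verdict": decision.verdict.value,
        "step1_irregular": decision.step1_irregular,
        "count_rr": decision.features.count_rr,
        "svd_ratio": decision.features.svd_ratio,
        "heart_rate": decision.features.heart_rate,
        "n_intervals": decision.features.n_intervals,
        "cluster_count": decision.cluster_count,
        "trace": decision.trace.splitlines(),
    }


def write_decisions_json(decisions: dict[str, Decision], path: str | Path) -> None:
    payload = [decision_to_dict(d, rid) for rid, d in decisions.items()]
    Path(path).write_text(json.dumps(payload, indent=2))


def write_manifest(records: list[ECGRecord], path: str | Path) -> None:
    """JSON manifest with ground truth for a simulated cohort."""
    payload = [
        {
            "record_id": r.record_id,
            "label": r.label.value,
            "sampling_rate": r.sampling_rate,
            "duration": r.duration,
            "true_r_times": [float(t) for t in r.true_r_times],
        }
        for r in records
    ]
    Path(path).write_text(json.dumps(payload, indent=2))
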