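"""Readers/writers for trace tables, experiment configs and run summaries.

Trace files are plain numeric CSV in two dialects:

* wide — one column per cell, one row per frame; an optional header row
  carries cell ids. The frame interval travels in the config, not the
  file (matching tracker/ROI-export reality).
* long — columns ``cell_id, time_s, value``.

Condition/replicate labels travel in config or a sidecar manifest so trace
files stay purely numeric.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any, Optional

import numpy as np
import pandas as pd
import yaml

from .traces import FluorescenceTrace, TraceSet

__all__ = [
    "ConfigError",
    "ExperimentConfig",
    "read_traces_wide",
    "read_traces_long",
    "write_traces_wide",
    "write_traces_long",
    "write_cell_metrics",
    "write_summary",
]

VERSION = "0.1.0"


class ConfigError(ValueError):
    """Invalid or incomplete experiment configuration."""


_REQUIRED_BY_KIND = {
    "agonist": ["frame_interval_s", "baseline_n_frames", "stimulus_frame"],
    "soce": ["frame_interval_s", "drug_time_s", "readd_time_s"],
    "dose_response": [],
    "optostim": [
        "frame_interval_s",
        "interval_s",
        "pulse_ms",
        "baseline_period_s",
        "total_duration_s",
    ],
}


@dataclass
class ExperimentConfig:
    """All tunables of an analysis run; every threshold named in the
    analysis conventions is exposed here."""

    kind: str
    frame_interval_s: float = 5.0
    baseline_n_frames: int = 10
    stimulus_frame: int = 10
    peak_threshold: float = 0.35
    depletion_threshold: float = 0.35
    opto_threshold: float = 0.125
    window_s: float = 16.0
    span_s: float = 30.0
    seed: int = 0
    protocol: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.kind not in _REQUIRED_BY_KIND:
            raise ConfigError(
                f"unknown analysis kind {self.kind!r}; expected one of "
                f"{sorted(_REQUIRED_BY_KIND)}"
            )
        for thr in ("peak_threshold", "depletion_threshold", "opto_threshold"):
            if getattr(self, thr) <= 0:
                raise ConfigError(f"{thr} must be positive")
        for name in _REQUIRED_BY_KIND[self.kind]:
            if hasattr(self, name):
                if getattr(self, name) is None:
                    raise ConfigError(f"missing required config field: {name}")
            elif name not in self.protocol:
                raise ConfigError(f"missing required config field: {name}")

    @classmethod
    def from_yaml(cls, path) -> "ExperimentConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "kind" not in raw:
            raise ConfigError("missing required config field: kind")
        known = {f for f in cls.__dataclass_fields__}
        top = {k: v for k, v in raw.items() if k in known}
        return cls(**top)

    def to_dict(self) -> dict:
        return asdict(self)

    @property
    def hash(self) -> str:
        """Stable digest of every effective parameter."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _fail_non_numeric(df: pd.DataFrame, path) -> pd.DataFrame:
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna() & df.notna()
    if bad.any().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise ValueError(
            f"{path}: non-numeric value {df.iat[r, c]!r} at row {r}, column "
            f"{df.columns[c]!r}"
        )
    if numeric.isna().any().any():
        r, c = np.argwhere(numeric.isna().to_numpy())[0]
        raise ValueError(
            f"{path}: missing value (ragged row?) at row {r}, column "
            f"{df.columns[c]!r}"
        )
    return numeric


def read_traces_wide(path, frame_interval_s: float) -> TraceSet:
    """Read a wide trace CSV (one column per cell, one row per frame).

    A header row of cell ids is detected automatically; without one the
    columns are named by position.
    """
    try:
        head = pd.read_csv(path, header=None, nrows=1)
    except pd.errors.EmptyDataError:
        raise ValueError(f"{path}: empty trace file") from None
    has_header = not all(
        pd.api.types.is_number(v) or _is_number_str(v) for v in head.iloc[0]
    )
    df = pd.read_csv(path, header=0 if has_header else None)
    if not has_header:
        df.columns = [f"cell_{i:04d}" for i in range(df.shape[1])]
    if df.shape[0] == 0:
        raise ValueError(f"{path}: no frames in trace file")
    df = _fail_non_numeric(df, path)
    times = np.arange(df.shape[0]) * frame_interval_s
    traces = [
        FluorescenceTrace(
            cell_id=str(col),
            times=times,
            values=df[col].to_numpy(dtype=float),
            frame_interval_s=frame_interval_s,
        )
        for col in df.columns
    ]
    return TraceSet(traces=traces, frame_interval_s=frame_interval_s)


def _is_number_str(v) -> bool:
    try:
        float(v)
        return True
    except (TypeError, ValueError):
        return False


def read_traces_long(path) -> TraceSet:
    """Read a long trace CSV with columns ``cell_id, time_s, value``.

    Rows may arrive unordered; they are sorted by time per cell. Duplicate
    (cell, time) pairs are an error.
    """
    df = pd.read_csv(path)
    required = {"cell_id", "time_s", "value"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    dup = df.duplicated(subset=["cell_id", "time_s"])
    if dup.any():
        row = df[dup].iloc[0]
        raise ValueError(
            f"{path}: duplicate entry for cell {row['cell_id']!r} at "
            f"t={row['time_s']} s"
        )
    df = df.sort_values(["cell_id", "time_s"], kind="stable")
    traces = []
    interval = None
    for cell_id, sub in df.groupby("cell_id", sort=True):
        times = sub["time_s"].to_numpy(dtype=float)
        if len(times) >= 2:
            interval = float(times[1] - times[0])
        traces.append(
            FluorescenceTrace(
                cell_id=str(cell_id),
                times=times,
                values=sub["value"].to_numpy(dtype=float),
                frame_interval_s=interval if interval is not None else 1.0,
            )
        )
    if not traces:
        raise ValueError(f"{path}: empty trace file")
    return TraceSet(traces=traces, frame_interval_s=traces[0].frame_interval_s)


def write_traces_wide(traces: TraceSet, path, header: bool = True) -> None:
    df = pd.DataFrame(
        {tr.cell_id: tr.values for tr in traces}
    )
    df.to_csv(path, index=False, header=header)


def write_traces_long(traces: TraceSet, path) -> None:
    rows = []
    for tr in traces:
        for t, v in zip(tr.times, tr.values):
            rows.append({"cell_id": tr.cell_id, "time_s": t, "value": v})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_cell_metrics(results: pd.DataFrame, path) -> None:
    """Per-cell metrics CSV with a stable column order; missing metrics are
    written as empty fields."""
    results.to_csv(path, index=False)


def write_summary(
    summary: dict,
    path,
    config: Optional[ExperimentConfig] = None,
    seed: Optional[int] = None,
) -> None:
    """JSON summary with run metadata (config hash, seed, version)."""
    payload: dict[str, Any] = {
        "version": VERSION,
        "seed": seed,
        "config_hash": config.hash if config is not None else None,
        "config": config.to_dict() if config is not None else None,
        "summary": summary,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=1, default=_json_default)


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")
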