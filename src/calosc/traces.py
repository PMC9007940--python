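"""Core in-memory containers for fluorescence time series.

A recording is a set of per-cell ROI intensity traces sampled on a shared,
uniform time grid. Raw traces carry arbitrary fluorescence units; normalized
traces are expressed as F/F0 fold-change of a pre-stimulus baseline.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = [
    "FluorescenceTrace",
    "NormalizedTrace",
    "TraceSet",
    "ExtremaSet",
    "PeakCall",
]

_REL_SPACING_TOL = 1e-6


@dataclass
class FluorescenceTrace:
    """One cell's raw intensity time series with a uniform frame interval."""

    cell_id: str
    times: np.ndarray
    values: np.ndarray
    frame_interval_s: float

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be 1-D")
        if len(self.times) != len(self.values):
            raise ValueError(
                f"times ({len(self.times)}) and values ({len(self.values)}) "
                "must have equal length"
            )
        if len(self.times) >= 2:
            dt = np.diff(self.times)
            if np.any(dt <= 0):
                raise ValueError("times must be strictly increasing")
            if np.any(np.abs(dt - self.frame_interval_s) > _REL_SPACING_TOL * self.frame_interval_s):
                raise ValueError("times must be uniformly spaced at frame_interval_s")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def duration_s(self) -> float:
        return float(self.times[-1] - self.times[0])


@dataclass
class NormalizedTrace:
    """F/F0-normalized trace; ``smoothed_values`` is filled by loess smoothing.

    ``baseline_window`` records the (start, end) frame slice used for F0.
    """

    cell_id: str
    times: np.ndarray
    norm_values: np.ndarray
    f0: float
    baseline_window: tuple[int, int]
    frame_interval_s: float
    smoothed_values: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.norm_values = np.asarray(self.norm_values, dtype=float)
        if self.f0 <= 0:
            raise ValueError(f"f0 must be positive, got {self.f0}")
        if self.smoothed_values is not None:
            self.smoothed_values = np.asarray(self.smoothed_values, dtype=float)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    def require_smoothed(self) -> np.ndarray:
        if self.smoothed_values is None:
            raise ValueError(
                f"trace {self.cell_id!r} has no smoothed values; run smooth_trace first"
            )
        return self.smoothed_values


@dataclass
class TraceSet:
    """A collection of traces sharing a frame grid, with condition metadata."""

    traces: list[FluorescenceTrace]
    frame_interval_s: float
    condition: str = ""
    replicate: str = ""

    def __post_init__(self) -> None:
        if self.traces:
            n0 = self.traces[0].n_frames
            for tr in self.traces:
                if tr.n_frames != n0:
                    raise ValueError("all traces in a TraceSet must share frame count")
                if abs(tr.frame_interval_s - self.frame_interval_s) > 1e-9:
                    raise ValueError("all traces must share the set's frame interval")

    def __len__(self) -> int:
        return len(self.traces)

    def __iter__(self):
        return iter(self.traces)

    @property
    def cell_ids(self) -> list[str]:
        return [tr.cell_id for tr in self.traces]

    def to_wide(self) -> "np.ndarray":
        return np.column_stack([tr.values for tr in self.traces])


@dataclass
class ExtremaSet:
    """Frame indices of local minima and maxima on a smoothed trace.

    After same-type merging, minima and maxima alternate along the trace.
    """

    minima_indices: np.ndarray
    maxima_indices: np.ndarray

    def __post_init__(self) -> None:
        self.minima_indices = np.asarray(self.minima_indices, dtype=int)
        self.maxima_indices = np.asarray(self.maxima_indices, dtype=int)


@dataclass
class PeakCall:
    """One detected calcium peak and its reference minimum.

    ``post_min_index`` is None when no minimum follows the peak before the
    recording ends (an on-going response).
    """

    peak_index: int
    peak_time_s: float
    preceding_min_index: int
    amplitude: float
    post_min_index: Optional[int] = None
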