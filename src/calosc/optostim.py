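"""Long-term optogenetic stimulation analysis and protocol design.

Long recordings (hours) drift, so a *rubberband* baseline — the lower
convex hull of the trace, i.e. its greatest convex minorant — is fitted
under each trace. Responsiveness is judged on the division-normalized
trace (>= 12.5% rise within 2 min of the first light pulse, after loess
fitting); total stimulated calcium flux is the AUC of the
subtraction-normalized trace over the stimulation period. Protocol design
converts pulse intervals to stimulation frequencies (mHz) and matches
total light exposure (duty cycle) across frequencies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .processing import loess
from .traces import FluorescenceTrace, TraceSet

__all__ = [
    "StimProtocol",
    "BaselineCurve",
    "OptoResult",
    "design_protocol",
    "match_exposure",
    "fit_rubberband_baseline",
    "normalize_by_division",
    "classify_opto_responsive",
    "stimulation_auc",
    "analyze_optostim",
]

OPTO_THRESHOLD = 0.125
OPTO_WINDOW_S = 120.0


@dataclass
class StimProtocol:
    """An optogenetic pulse schedule with derived frequency and duty cycle."""

    baseline_period_s: float
    interval_s: float
    pulse_ms: float
    total_duration_s: float

    def __post_init__(self) -> None:
        if min(self.baseline_period_s, self.interval_s, self.pulse_ms, self.total_duration_s) <= 0:
            raise ValueError("all protocol fields must be positive")
        if self.pulse_ms >= self.interval_s * 1000.0:
            raise ValueError(
                f"pulse of {self.pulse_ms} ms does not fit in a "
                f"{self.interval_s} s interval"
            )

    @property
    def frequency_mHz(self) -> float:
        return 1000.0 / self.interval_s

    @property
    def frequency_mHz_reported(self) -> float:
        """Frequency truncated to two decimals, the conventional label
        (e.g. 1/1800 s -> 0.55 mHz)."""
        return math.floor(self.frequency_mHz * 100.0) / 100.0

    @property
    def duty(self) -> float:
        return self.pulse_ms / 1000.0 / self.interval_s

    @property
    def pulse_times(self) -> np.ndarray:
        """Pulse onset times: every ``interval_s`` from the end of the
        no-stimulation baseline period to the end of the recording."""
        return np.arange(
            self.baseline_period_s, self.total_duration_s, self.interval_s
        )


def design_protocol(
    interval_s: float,
    pulse_ms: float,
    baseline_period_s: float,
    total_duration_s: float,
) -> StimProtocol:
    """Build a stimulation protocol from its four defining quantities."""
    return StimProtocol(
        baseline_period_s=baseline_period_s,
        interval_s=interval_s,
        pulse_ms=pulse_ms,
        total_duration_s=total_duration_s,
    )


def match_exposure(protocol_a: StimProtocol, interval_b_s: float) -> float:
    """Pulse duration (ms) giving protocol B the same duty cycle as A.

    Exact duty equality: pulse_b = duty_a * interval_b * 1000.
    """
    if interval_b_s <= 0:
        raise ValueError("interval_b_s must be positive")
    pulse_b = protocol_a.duty * interval_b_s * 1000.0
    if pulse_b >= interval_b_s * 1000.0:
        raise ValueError("matched pulse would exceed the target interval")
    return pulse_b


@dataclass
class BaselineCurve:
    """Piecewise-linear rubberband baseline: the greatest convex minorant
    of the (time, value) points, evaluated at every frame."""

    values: np.ndarray
    knot_indices: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.knot_indices = np.asarray(self.knot_indices, dtype=int)


@dataclass
class OptoResult:
    cell_id: str
    responsive: bool
    stim_auc: float


def fit_rubberband_baseline(
    times: np.ndarray, values: np.ndarray
) -> BaselineCurve:
    """Lower convex hull of the trace (Andrew monotone chain), evaluated at
    every frame by linear interpolation between hull vertices."""
    times = np.asarray(times, dtype=float)
    values = np.asarray(values, dtype=float)
    n = len(times)
    if n < 3:
        raise ValueError("rubberband baseline requires at least 3 frames")
    hull: list[int] = []
    for i in range(n):
        while len(hull) >= 2:
            o, a = hull[-2], hull[-1]
            cross = (times[a] - times[o]) * (values[i] - values[o]) - (
                values[a] - values[o]
            ) * (times[i] - times[o])
            if cross <= 0:
                hull.pop()
            else:
                break
        hull.append(i)
    knots = np.asarray(hull, dtype=int)
    baseline = np.interp(times, times[knots], values[knots])
    return BaselineCurve(values=baseline, knot_indices=knots)


def normalize_by_division(
    values: np.ndarray, baseline: BaselineCurve
) -> np.ndarray:
    """Fold-of-baseline trace: value / baseline (baseline must be positive)."""
    if np.any(baseline.values <= 0):
        raise ValueError("baseline curve must be positive for division normalization")
    return np.asarray(values, dtype=float) / baseline.values


def classify_opto_responsive(
    norm_values: np.ndarray,
    times: np.ndarray,
    first_pulse_time_s: float,
    threshold: float = OPTO_THRESHOLD,
    window_s: float = OPTO_WINDOW_S,
    span_s: float = 60.0,
) -> bool:
    """Responsive iff the loess-fitted division-normalized trace rises
    >= ``threshold`` above 1 within ``window_s`` after the first pulse."""
    times = np.asarray(times, dtype=float)
    if not (times[0] <= first_pulse_time_s <= times[-1]):
        raise ValueError("first pulse time outside the recording")
    duration = times[-1] - times[0]
    fitted = loess(times, np.asarray(norm_values, dtype=float), span_s / duration)
    mask = (times > first_pulse_time_s) & (times <= first_pulse_time_s + window_s)
    return bool(np.any(fitted[mask] >= 1.0 + threshold))


def stimulation_auc(
    values: np.ndarray,
    baseline: BaselineCurve,
    times: np.ndarray,
    protocol: StimProtocol,
) -> float:
    """AUC of (value - baseline) from the first pulse to the recording end."""
    times = np.asarray(times, dtype=float)
    pulses = protocol.pulse_times
    if pulses.size == 0:
        raise ValueError("protocol has no pulses inside the recording")
    mask = times >= pulses[0]
    if not np.any(mask):
        raise ValueError("stimulation period is empty")
    resid = np.asarray(values, dtype=float)[mask] - baseline.values[mask]
    return float(np.trapezoid(resid, times[mask]))


def analyze_optostim(
    traces: TraceSet,
    protocol: StimProtocol,
    threshold: float = OPTO_THRESHOLD,
    window_s: float = OPTO_WINDOW_S,
    span_s: float = 60.0,
) -> pd.DataFrame:
    """Rubberband-correct, classify and integrate every tracked cell."""
    first_pulse = float(protocol.pulse_times[0])
    rows = []
    for tr in traces:
        baseline = fit_rubberband_baseline(tr.times, tr.values)
        norm = normalize_by_division(tr.values, baseline)
        responsive = classify_opto_responsive(
            norm, tr.times, first_pulse, threshold, window_s, span_s
        )
        auc = stimulation_auc(tr.values, baseline, tr.times, protocol)
        rows.append(
            {"cell_id": tr.cell_id, "responsive": responsive, "stim_auc": auc}
        )
    return pd.DataFrame(rows)
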