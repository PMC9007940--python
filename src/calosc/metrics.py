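"""Per-cell response classification, oscillation metrics and condition summaries.

Definitions: a *responsive* cell has at least one called calcium peak; an
*oscillatory* cell has two or more. Response duration runs from the local
minimum before the first peak to the local minimum after the last peak (or
the end of the recording for an on-going response). Oscillation frequency
is peaks per response duration, reported in mHz. AUC integrates the
normalized trace above the F0 baseline (norm = 1) over the response span.
Per-cell AUC and frequency are strongly right-skewed and are therefore
log10-transformed for population summaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .traces import ExtremaSet, NormalizedTrace, PeakCall

__all__ = [
    "CellResponse",
    "ConditionSummary",
    "classify_response",
    "response_duration",
    "oscillation_frequency",
    "response_auc",
    "log_transform_metrics",
    "summarize_condition",
    "analyze_cell",
    "responses_to_frame",
]


@dataclass
class CellResponse:
    """Per-cell metric record."""

    cell_id: str
    responsive: bool
    oscillatory: bool
    n_peaks: int
    max_amplitude: Optional[float] = None
    duration_min: Optional[float] = None
    frequency_mHz: Optional[float] = None
    auc: float = 0.0
    log10_auc: Optional[float] = None
    log10_frequency: Optional[float] = None


@dataclass
class ConditionSummary:
    """Population summary for one condition (Table-style columns).

    When replicate labels are given, means and SEMs are computed across
    replicate means; with a single replicate (or none) the SEM across
    replicates is undefined and reported as NaN.
    """

    n_cells: int
    n_replicates: int
    pct_responsive: float
    pct_responsive_sem: float
    pct_oscillatory: float
    pct_oscillatory_sem: float
    mean_max_amplitude: float
    max_amplitude_sem: float
    mean_duration_min: float
    duration_sem: float
    mean_log10_auc: float
    log10_auc_sem: float
    mean_frequency_mHz: float
    frequency_sem: float

    def to_dict(self) -> dict:
        return asdict(self)


def classify_response(peaks: Sequence[PeakCall]) -> tuple[bool, bool]:
    """(responsive, oscillatory) = (>=1 peak, >=2 peaks)."""
    n = len(peaks)
    return n >= 1, n >= 2


def _response_span_indices(
    peaks: Sequence[PeakCall], n_frames: int
) -> tuple[int, int]:
    """Frame span from the pre-first-peak minimum to the post-last-peak
    minimum, or the last frame if the response is on-going."""
    start = peaks[0].preceding_min_index
    post = peaks[-1].post_min_index
    end = post if post is not None else n_frames - 1
    return start, end


def response_duration(
    peaks: Sequence[PeakCall], times: np.ndarray
) -> float:
    """Response duration in minutes (see module docstring for endpoints)."""
    if not peaks:
        raise ValueError("response_duration requires at least one peak")
    start, end = _response_span_indices(peaks, len(times))
    return float(times[end] - times[start]) / 60.0


def oscillation_frequency(n_peaks: int, duration_min: float) -> float:
    """Oscillation frequency in mHz: peaks divided by response duration."""
    if n_peaks < 2:
        raise ValueError("frequency is defined only for oscillatory cells (>=2 peaks)")
    if duration_min <= 0:
        raise ValueError("duration must be positive")
    return n_peaks / (duration_min * 60.0) * 1000.0


def response_auc(norm: NormalizedTrace, peaks: Sequence[PeakCall]) -> float:
    """Trapezoidal integral of (F/F0 - 1) over the response span.

    Negative excursions are included as-is. Cells with zero peaks return 0
    by convention and are excluded from AUC summaries.
    """
    if not peaks:
        return 0.0
    start, end = _response_span_indices(peaks, norm.n_frames)
    y = norm.norm_values[start : end + 1] - 1.0
    t = norm.times[start : end + 1]
    return float(np.trapezoid(y, t))


def log_transform_metrics(
    values: np.ndarray,
) -> tuple[np.ndarray, int]:
    """Base-10 log of positive values; non-positive entries become NaN.

    Returns the transformed array and the count of dropped (non-positive)
    entries; a warning is emitted when any are dropped.
    """
    values = np.asarray(values, dtype=float)
    bad = ~(values > 0)
    n_bad = int(np.sum(bad))
    if n_bad:
        warnings.warn(
            f"{n_bad} non-positive value(s) dropped before log10 transform",
            stacklevel=2,
        )
    out = np.full(values.shape, np.nan)
    out[~bad] = np.log10(values[~bad])
    return out, n_bad


def analyze_cell(
    norm: NormalizedTrace,
    extrema: ExtremaSet,
    peaks: Sequence[PeakCall],
) -> CellResponse:
    """Assemble the per-cell metric record from pipeline outputs."""
    responsive, oscillatory = classify_response(peaks)
    if not responsive:
        return CellResponse(
            cell_id=norm.cell_id, responsive=False, oscillatory=False, n_peaks=0
        )
    duration = response_duration(peaks, norm.times)
    auc = response_auc(norm, peaks)
    freq = oscillation_frequency(len(peaks), duration) if oscillatory else None
    return CellResponse(
        cell_id=norm.cell_id,
        responsive=True,
        oscillatory=oscillatory,
        n_peaks=len(peaks),
        max_amplitude=max(p.amplitude for p in peaks),
        duration_min=duration,
        frequency_mHz=freq,
        auc=auc,
        log10_auc=float(np.log10(auc)) if auc > 0 else None,
        log10_frequency=float(np.log10(freq)) if freq else None,
    )


def responses_to_frame(cells: Sequence[CellResponse]) -> pd.DataFrame:
    """One row per cell, stable column order."""
    return pd.DataFrame([asdict(c) for c in cells])


def _mean_sem(values: np.ndarray) -> tuple[float, float]:
    values = np.asarray(values, dtype=float)
    values = values[~np.isnan(values)]
    if values.size == 0:
        return float("nan"), float("nan")
    mean = float(np.mean(values))
    if values.size < 2:
        return mean, float("nan")
    return mean, float(np.std(values, ddof=1) / np.sqrt(values.size))


def _replicate_stats(df: pd.DataFrame) -> dict[str, float]:
    resp = df["responsive"].astype(bool)
    osc = df["oscillatory"].astype(bool)
    out = {
        "pct_responsive": 100.0 * resp.mean(),
        "pct_oscillatory": (
            100.0 * osc[resp].mean() if resp.any() else np.nan
        ),
        "max_amplitude": df.loc[resp, "max_amplitude"].mean() if resp.any() else np.nan,
        "duration_min": df.loc[resp, "duration_min"].mean() if resp.any() else np.nan,
    }
    auc = df.loc[resp & (df["auc"] > 0), "auc"]
    out["log10_auc"] = np.log10(auc).mean() if len(auc) else np.nan
    freq = df.loc[osc, "frequency_mHz"].astype(float)
    out["frequency_mHz"] = freq.mean() if len(freq) else np.nan
    return out


def summarize_condition(
    cells: Sequence[CellResponse] | pd.DataFrame,
    replicate_labels: Optional[Sequence] = None,
) -> ConditionSummary:
    """Population summary with replicate-aware SEMs.

    With replicate labels, each metric is averaged within replicates first
    and the SEM is taken across replicate means (matching per-sample
    averaging of biological replicates). Without labels, statistics are
    taken across cells. ``pct_oscillatory`` is computed among responsive
    cells only.
    """
    df = cells if isinstance(cells, pd.DataFrame) else responses_to_frame(cells)
    if len(df) == 0:
        raise ValueError("summarize_condition requires at least one cell")
    if replicate_labels is not None:
        if len(replicate_labels) != len(df):
            raise ValueError("one replicate label per cell required")
        groups = [
            _replicate_stats(sub)
            for _, sub in df.groupby(np.asarray(replicate_labels), sort=True)
        ]
        stats = pd.DataFrame(groups)
        n_rep = len(groups)

        def ms(col: str) -> tuple[float, float]:
            return _mean_sem(stats[col].to_numpy())

        pr, pr_sem = ms("pct_responsive")
        po, po_sem = ms("pct_oscillatory")
        ma, ma_sem = ms("max_amplitude")
        du, du_sem = ms("duration_min")
        la, la_sem = ms("log10_auc")
        fr, fr_sem = ms("frequency_mHz")
    else:
        # per-cell statistics when no replicate structure is known
        n_rep = 1
        resp = df["responsive"].astype(bool).to_numpy()
        osc = df["oscillatory"].astype(bool).to_numpy()
        pr, pr_sem = _mean_sem(100.0 * resp.astype(float))
        po, po_sem = _mean_sem(100.0 * osc[resp].astype(float))
        ma, ma_sem = _mean_sem(df.loc[resp, "max_amplitude"].to_numpy(dtype=float))
        du, du_sem = _mean_sem(df.loc[resp, "duration_min"].to_numpy(dtype=float))
        auc = df.loc[resp & (df["auc"] > 0), "auc"].to_numpy(dtype=float)
        la, la_sem = _mean_sem(np.log10(auc) if auc.size else np.array([]))
        fr, fr_sem = _mean_sem(df.loc[osc, "frequency_mHz"].to_numpy(dtype=float))
    return ConditionSummary(
        n_cells=len(df),
        n_replicates=n_rep,
        pct_responsive=pr,
        pct_responsive_sem=pr_sem,
        pct_oscillatory=po,
        pct_oscillatory_sem=po_sem,
        mean_max_amplitude=ma,
        max_amplitude_sem=ma_sem,
        mean_duration_min=du,
        duration_sem=du_sem,
        mean_log10_auc=la,
        log10_auc_sem=la_sem,
        mean_frequency_mHz=fr,
        frequency_sem=fr_sem,
    )
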