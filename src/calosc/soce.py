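"""Store-operated calcium entry (SOCE) assay quantification.

Cells imaged in calcium-free medium receive a store-depleting stimulus
(thapsigargin or a muscarinic agonist); extracellular calcium is
re-introduced 10-15 min later. Quantification per cell:

* inclusion — the smoothed F/F0 trace must rise >= 0.35 fold-change above
  baseline between drug addition and calcium re-addition (cells without an
  ER-depletion response are excluded);
* ER-depletion AUC and maximum amplitude over a fixed window (default
  10 min) after drug addition;
* SOCE AUC and maximum amplitude over a fixed window (default 8 min)
  after calcium re-addition; windows must be matched across compared
  conditions;
* condition-level SOCE normalized to the ER release of matched control
  replicates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, asdict
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .processing import (
    DEFAULT_SPAN_S,
    normalize_to_baseline,
    smooth_trace,
)
from .traces import FluorescenceTrace, NormalizedTrace, TraceSet

__all__ = [
    "SOCEProtocol",
    "SOCEResult",
    "detect_store_depletion",
    "er_depletion_metrics",
    "soce_metrics",
    "analyze_soce_cell",
    "analyze_soce",
    "normalize_soce",
    "require_matched_windows",
]

DEPLETION_THRESHOLD = 0.35


@dataclass
class SOCEProtocol:
    """Timing and windows of a store-depletion / re-addition experiment."""

    drug_time_s: float
    readd_time_s: float
    er_window_s: float = 600.0
    soce_window_s: float = 480.0
    depletion_threshold: float = DEPLETION_THRESHOLD
    baseline_n_frames: int = 10

    def __post_init__(self) -> None:
        if self.drug_time_s >= self.readd_time_s:
            raise ValueError("drug_time_s must precede readd_time_s")
        if self.er_window_s <= 0 or self.soce_window_s <= 0:
            raise ValueError("analysis windows must be positive")
        if self.depletion_threshold <= 0:
            raise ValueError("depletion_threshold must be positive")


@dataclass
class SOCEResult:
    """Per-cell SOCE quantification; excluded cells carry no metrics."""

    cell_id: str
    included: bool
    er_auc: Optional[float] = None
    er_max_amplitude: Optional[float] = None
    soce_auc: Optional[float] = None
    soce_max_amplitude: Optional[float] = None
    normalized_soce: Optional[float] = None


def require_matched_windows(*protocols: SOCEProtocol) -> None:
    """SOCE AUC windows must be identical across compared conditions."""
    windows = {p.soce_window_s for p in protocols}
    if len(windows) > 1:
        raise ValueError(
            f"conditions use unmatched SOCE windows {sorted(windows)}; "
            "AUC durations must be matched between compared conditions"
        )


def detect_store_depletion(norm: NormalizedTrace, protocol: SOCEProtocol) -> bool:
    """Included iff the smoothed trace rises >= threshold above baseline
    anywhere in [drug_time_s, readd_time_s)."""
    if protocol.drug_time_s > norm.times[-1]:
        raise ValueError("drug_time_s is outside the recording")
    s = norm.require_smoothed()
    mask = (norm.times >= protocol.drug_time_s) & (norm.times < protocol.readd_time_s)
    return bool(np.any(s[mask] >= 1.0 + protocol.depletion_threshold))


def _window_slice(times: np.ndarray, start_s: float, stop_s: float) -> np.ndarray:
    return (times >= start_s) & (times <= stop_s)


def er_depletion_metrics(
    norm: NormalizedTrace, protocol: SOCEProtocol
) -> tuple[float, float]:
    """(er_auc, er_max_amplitude) over [drug_time, drug_time + er_window].

    The ER window must end no later than calcium re-addition so SOCE influx
    can never leak into depletion metrics.
    """
    stop = protocol.drug_time_s + protocol.er_window_s
    if stop > protocol.readd_time_s:
        raise ValueError(
            f"ER window ends at {stop} s, after calcium re-addition at "
            f"{protocol.readd_time_s} s; windows must not overlap"
        )
    mask = _window_slice(norm.times, protocol.drug_time_s, stop)
    auc = float(np.trapezoid(norm.norm_values[mask] - 1.0, norm.times[mask]))
    s = norm.require_smoothed()
    max_amp = float(np.max(s[mask]) - 1.0)
    return auc, max_amp


def soce_metrics(
    norm: NormalizedTrace, protocol: SOCEProtocol
) -> tuple[float, float]:
    """(soce_auc, soce_max_amplitude) over [readd_time, readd_time + window].

    A window running past the end of the recording is truncated with a
    warning.
    """
    stop = protocol.readd_time_s + protocol.soce_window_s
    if stop > norm.times[-1]:
        warnings.warn(
            f"SOCE window truncated at recording end ({norm.times[-1]} s < {stop} s)",
            stacklevel=2,
        )
        stop = float(norm.times[-1])
    mask = _window_slice(norm.times, protocol.readd_time_s, stop)
    auc = float(np.trapezoid(norm.norm_values[mask] - 1.0, norm.times[mask]))
    s = norm.require_smoothed()
    max_amp = float(np.max(s[mask]) - 1.0)
    return auc, max_amp


def analyze_soce_cell(
    trace: FluorescenceTrace,
    protocol: SOCEProtocol,
    span_s: float = DEFAULT_SPAN_S,
) -> SOCEResult:
    """Normalize (F0 before drug addition), smooth, and quantify one cell."""
    drug_frame = int(np.searchsorted(trace.times, protocol.drug_time_s))
    norm = normalize_to_baseline(
        trace, protocol.baseline_n_frames, stimulus_frame=drug_frame
    )
    norm = smooth_trace(norm, span_s)
    if not detect_store_depletion(norm, protocol):
        return SOCEResult(cell_id=trace.cell_id, included=False)
    er_auc, er_max = er_depletion_metrics(norm, protocol)
    soce_auc, soce_max = soce_metrics(norm, protocol)
    return SOCEResult(
        cell_id=trace.cell_id,
        included=True,
        er_auc=er_auc,
        er_max_amplitude=er_max,
        soce_auc=soce_auc,
        soce_max_amplitude=soce_max,
    )


def analyze_soce(
    traces: TraceSet,
    protocol: SOCEProtocol,
    span_s: float = DEFAULT_SPAN_S,
) -> pd.DataFrame:
    """Per-cell SOCE results as a DataFrame (one row per cell)."""
    results = [analyze_soce_cell(tr, protocol, span_s) for tr in traces]
    return pd.DataFrame([asdict(r) for r in results])


def normalize_soce(
    condition_results: pd.DataFrame,
    control_er_auc_per_replicate: Mapping,
    replicate_labels: Optional[Sequence] = None,
) -> tuple[float, float, pd.Series]:
    """Normalize condition SOCE to control ER release, replicate-matched.

    Per replicate: mean included-cell ``soce_auc`` of the condition divided
    by the mean control ``er_auc`` of the same replicate. Returns
    (mean, SEM across replicates, per-replicate series). ``condition_results``
    needs columns ``included``, ``soce_auc`` and either a ``replicate``
    column or explicit ``replicate_labels``.
    """
    df = condition_results.copy()
    if replicate_labels is not None:
        df["replicate"] = list(replicate_labels)
    if "replicate" not in df.columns:
        raise ValueError("replicate labels required for SOCE normalization")
    df = df[df["included"].astype(bool)]
    ratios = {}
    for rep, sub in df.groupby("replicate", sort=True):
        if rep not in control_er_auc_per_replicate:
            raise ValueError(f"no matched control ER release for replicate {rep!r}")
        control_er = control_er_auc_per_replicate[rep]
        if control_er == 0:
            raise ValueError(f"control ER release is zero for replicate {rep!r}")
        ratios[rep] = float(sub["soce_auc"].mean()) / float(control_er)
    per_rep = pd.Series(ratios).sort_index()
    mean = float(per_rep.mean())
    sem = (
        float(per_rep.std(ddof=1) / np.sqrt(len(per_rep)))
        if len(per_rep) > 1
        else float("nan")
    )
    return mean, sem, per_rep
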