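"""End-to-end per-recording analysis entry points."""

from __future__ import annotations

from typing import Optional, Sequence

import pandas as pd

from .metrics import (
    CellResponse,
    ConditionSummary,
    analyze_cell,
    responses_to_frame,
    summarize_condition,
)
from .processing import (
    DEFAULT_BASELINE_N_FRAMES,
    DEFAULT_SPAN_S,
    EXTREMA_WINDOW_S,
    PEAK_THRESHOLD,
    process_trace,
)
from .traces import TraceSet

__all__ = ["analyze_traceset"]


def analyze_traceset(
    traces: TraceSet,
    baseline_n_frames: int = DEFAULT_BASELINE_N_FRAMES,
    stimulus_frame: Optional[int] = None,
    span_s: float = DEFAULT_SPAN_S,
    window_s: float = EXTREMA_WINDOW_S,
    threshold: float = PEAK_THRESHOLD,
    replicate_labels: Optional[Sequence] = None,
) -> tuple[pd.DataFrame, ConditionSummary]:
    """Run normalize/smooth/extrema/peaks/metrics on every cell.

    Returns the per-cell metrics table and the condition summary.
    """
    cells: list[CellResponse] = []
    for tr in traces:
        norm, extrema, peaks = process_trace(
            tr,
            baseline_n_frames=baseline_n_frames,
            stimulus_frame=stimulus_frame,
            span_s=span_s,
            window_s=window_s,
            threshold=threshold,
        )
        cells.append(analyze_cell(norm, extrema, peaks))
    table = responses_to_frame(cells)
    summary = summarize_condition(table, replicate_labels)
    return table, summary
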