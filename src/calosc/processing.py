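"""Baseline normalization, loess smoothing, extrema detection and peak calling.

The per-cell pipeline is:

1. ``normalize_to_baseline`` — divide by F0, the mean of the frames
   immediately preceding stimulus addition (F/F0 fold-change).
2. ``smooth_trace`` — locally weighted quadratic (loess) smoothing.
3. ``find_local_extrema`` — local minima/maxima in sliding windows
   (default 16 s, i.e. +/-8 s around each frame).
4. ``call_peaks`` — retain maxima rising >= 0.35 fold-change above the
   preceding local minimum.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.ndimage import maximum_filter1d, minimum_filter1d

from .traces import ExtremaSet, FluorescenceTrace, NormalizedTrace, PeakCall

__all__ = [
    "PEAK_THRESHOLD",
    "EXTREMA_WINDOW_S",
    "DEFAULT_SPAN_S",
    "DEFAULT_BASELINE_N_FRAMES",
    "normalize_to_baseline",
    "loess",
    "smooth_trace",
    "find_local_extrema",
    "call_peaks",
    "process_trace",
]

#: Minimum fold-change above the preceding minimum for a maximum to count as
#: a calcium peak (inclusive).
PEAK_THRESHOLD = 0.35
#: Width of the sliding extrema window, seconds (centered: +/- half-width).
EXTREMA_WINDOW_S = 16.0
#: Default loess span in seconds.
DEFAULT_SPAN_S = 30.0
#: Default number of pre-stimulus frames averaged into F0.
DEFAULT_BASELINE_N_FRAMES = 10


def normalize_to_baseline(
    trace: FluorescenceTrace,
    baseline_n_frames: int = DEFAULT_BASELINE_N_FRAMES,
    stimulus_frame: int | None = None,
) -> NormalizedTrace:
    """Divide a raw trace by F0, the mean of ``baseline_n_frames`` frames
    immediately preceding ``stimulus_frame``.

    If ``stimulus_frame`` is None the first ``baseline_n_frames`` frames are
    used (stimulus at frame ``baseline_n_frames``).
    """
    if stimulus_frame is None:
        stimulus_frame = baseline_n_frames
    if baseline_n_frames < 5:
        raise ValueError(
            f"baseline_n_frames must be >= 5, got {baseline_n_frames}"
        )
    if stimulus_frame < baseline_n_frames:
        raise ValueError(
            f"stimulus_frame ({stimulus_frame}) precedes the "
            f"{baseline_n_frames}-frame baseline window"
        )
    if stimulus_frame > trace.n_frames:
        raise ValueError("stimulus_frame beyond end of recording")
    lo, hi = stimulus_frame - baseline_n_frames, stimulus_frame
    f0 = float(np.mean(trace.values[lo:hi]))
    if f0 <= 0:
        raise ValueError(
            f"non-positive baseline F0 ({f0}) for cell {trace.cell_id!r}"
        )
    return NormalizedTrace(
        cell_id=trace.cell_id,
        times=trace.times,
        norm_values=trace.values / f0,
        f0=f0,
        baseline_window=(lo, hi),
        frame_interval_s=trace.frame_interval_s,
    )


def loess(x: np.ndarray, y: np.ndarray, span_frac: float, degree: int = 2) -> np.ndarray:
    """Locally weighted polynomial regression with tricube weights.

    ``span_frac`` is the fraction of points in each local neighborhood
    (k nearest by distance in x). Endpoints use the same local fit with a
    one-sided neighborhood. Degree-2 local fits reproduce constants and
    straight lines exactly.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = len(x)
    if n == 0:
        return y.copy()
    if not (0 < span_frac <= 1):
        raise ValueError(f"span fraction must be in (0, 1], got {span_frac}")
    k = int(np.ceil(span_frac * n))
    k = max(k, degree + 2)
    k = min(k, n)
    out = np.empty(n)
    for i in range(n):
        d = np.abs(x - x[i])
        idx = np.argpartition(d, k - 1)[:k]
        di = d[idx]
        dmax = di.max()
        if dmax == 0:
            out[i] = float(np.mean(y[idx]))
            continue
        w = (1.0 - (di / dmax) ** 3) ** 3
        # keep the farthest point weakly in the fit for conditioning
        w = np.maximum(w, 1e-6)
        xs = x[idx] - x[i]
        coef = np.polyfit(xs, y[idx], deg=degree, w=np.sqrt(w))
        out[i] = coef[-1]
    return out


def smooth_trace(norm: NormalizedTrace, span_s: float = DEFAULT_SPAN_S) -> NormalizedTrace:
    """Loess-smooth a normalized trace with a span given in seconds."""
    duration = norm.times[-1] - norm.times[0]
    if span_s < 2 * norm.frame_interval_s:
        raise ValueError(
            f"span_s ({span_s}) must be at least two frame intervals "
            f"({2 * norm.frame_interval_s})"
        )
    if span_s > duration:
        raise ValueError(
            f"span_s ({span_s}) exceeds the trace duration ({duration})"
        )
    span_frac = span_s / duration
    smoothed = loess(norm.times, norm.norm_values, span_frac, degree=2)
    return replace(norm, smoothed_values=smoothed)


def _window_half_frames(window_s: float, frame_interval_s: float) -> int:
    half = int(np.floor(window_s / 2 / frame_interval_s + 1e-9))
    if half < 1:
        raise ValueError(
            f"extrema window of {window_s} s covers fewer than 2 frames at "
            f"{frame_interval_s} s sampling"
        )
    return half


def find_local_extrema(
    norm: NormalizedTrace, window_s: float = EXTREMA_WINDOW_S
) -> ExtremaSet:
    """Find local minima/maxima of the smoothed trace in centered windows.

    Frame ``i`` is a maximum iff ``smoothed[i]`` is >= every other value
    within ``+/- window_s/2`` seconds, strictly greater than at least one of
    them, and no earlier frame in the window ties it (plateaus keep their
    earliest frame). Minima are symmetric. Windows truncate at the trace
    edges. Consecutive same-type extrema are merged, keeping the more
    extreme value (earliest on ties), so minima and maxima alternate.
    """
    s = norm.require_smoothed()
    n = len(s)
    half = _window_half_frames(window_s, norm.frame_interval_s)
    size = 2 * half + 1

    win_max = maximum_filter1d(s, size=size, mode="constant", cval=-np.inf)
    win_min = minimum_filter1d(s, size=size, mode="constant", cval=np.inf)

    maxima, minima = [], []
    for i in range(n):
        lo, hi = max(0, i - half), min(n, i + half + 1)
        if s[i] == win_max[i]:
            w = s[lo:hi]
            if np.any(w < s[i]) and not np.any(s[lo:i] == s[i]):
                maxima.append(i)
        if s[i] == win_min[i]:
            w = s[lo:hi]
            if np.any(w > s[i]) and not np.any(s[lo:i] == s[i]):
                minima.append(i)

    minima, maxima = _merge_alternating(s, minima, maxima)
    return ExtremaSet(minima_indices=minima, maxima_indices=maxima)


def _merge_alternating(
    s: np.ndarray, minima: list[int], maxima: list[int]
) -> tuple[np.ndarray, np.ndarray]:
    """Merge runs of same-type extrema so minima and maxima alternate."""
    tagged = sorted([(i, "min") for i in minima] + [(i, "max") for i in maxima])
    kept: list[tuple[int, str]] = []
    for idx, kind in tagged:
        if kept and kept[-1][1] == kind:
            prev_idx = kept[-1][0]
            better = (s[idx] > s[prev_idx]) if kind == "max" else (s[idx] < s[prev_idx])
            if better:  # ties keep the earlier frame
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    out_min = np.array([i for i, k in kept if k == "min"], dtype=int)
    out_max = np.array([i for i, k in kept if k == "max"], dtype=int)
    return out_min, out_max


def call_peaks(
    extrema: ExtremaSet,
    norm: NormalizedTrace,
    threshold: float = PEAK_THRESHOLD,
) -> list[PeakCall]:
    """Call calcium peaks: maxima whose smoothed amplitude above the
    preceding local minimum is >= ``threshold`` (inclusive).

    A maximum with no preceding minimum is referenced to the first frame.
    ``post_min_index`` is the first minimum after the peak, or None if the
    response is still on-going at the end of the recording.
    """
    s = norm.require_smoothed()
    minima = extrema.minima_indices
    peaks: list[PeakCall] = []
    for m in extrema.maxima_indices:
        before = minima[minima < m]
        ref = int(before[-1]) if len(before) else 0
        amplitude = float(s[m] - s[ref])
        if amplitude < threshold:
            continue
        after = minima[minima > m]
        post = int(after[0]) if len(after) else None
        peaks.append(
            PeakCall(
                peak_index=int(m),
                peak_time_s=float(norm.times[m]),
                preceding_min_index=ref,
                amplitude=amplitude,
                post_min_index=post,
            )
        )
    return peaks


def process_trace(
    trace: FluorescenceTrace,
    baseline_n_frames: int = DEFAULT_BASELINE_N_FRAMES,
    stimulus_frame: int | None = None,
    span_s: float = DEFAULT_SPAN_S,
    window_s: float = EXTREMA_WINDOW_S,
    threshold: float = PEAK_THRESHOLD,
) -> tuple[NormalizedTrace, ExtremaSet, list[PeakCall]]:
    """Run the full normalize/smooth/extrema/peak pipeline on one trace."""
    norm = normalize_to_baseline(trace, baseline_n_frames, stimulus_frame)
    norm = smooth_trace(norm, span_s)
    extrema = find_local_extrema(norm, window_s)
    peaks = call_peaks(extrema, norm, threshold)
    return norm, extrema, peaks
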