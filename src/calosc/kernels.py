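"""Calcium transient kernel: difference of exponentials, unit peak height.

GCaMP-style transients rise fast and decay slowly. The kernel

    k(t) = exp(-t / tau_decay) - exp(-t / tau_rise),   t >= 0

is rescaled so its maximum equals 1; an event of amplitude ``a`` then
contributes ``a * k(t - t_event) / k_max`` in fold-change units.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "transient_kernel",
    "kernel_peak_time",
    "kernel_area",
]


def kernel_peak_time(rise_s: float, decay_s: float) -> float:
    """Time of the kernel maximum after event onset (seconds)."""
    _validate(rise_s, decay_s)
    return rise_s * decay_s / (decay_s - rise_s) * np.log(decay_s / rise_s)


def _validate(rise_s: float, decay_s: float) -> None:
    if rise_s <= 0 or decay_s <= 0:
        raise ValueError("rise and decay constants must be positive")
    if rise_s >= decay_s:
        raise ValueError(
            f"rise time ({rise_s}) must be shorter than decay time ({decay_s})"
        )


def _peak_height(rise_s: float, decay_s: float) -> float:
    tp = kernel_peak_time(rise_s, decay_s)
    return np.exp(-tp / decay_s) - np.exp(-tp / rise_s)


def transient_kernel(t: np.ndarray, rise_s: float, decay_s: float) -> np.ndarray:
    """Evaluate the unit-maximum kernel at times ``t`` (zero for t < 0)."""
    _validate(rise_s, decay_s)
    t = np.asarray(t, dtype=float)
    out = np.zeros_like(t)
    pos = t >= 0
    tp = t[pos]
    out[pos] = np.exp(-tp / decay_s) - np.exp(-tp / rise_s)
    return out / _peak_height(rise_s, decay_s)


def kernel_area(rise_s: float, decay_s: float) -> float:
    """Analytic integral of the unit-maximum kernel over [0, inf) in seconds.

    The unnormalized difference of exponentials integrates to
    ``decay_s - rise_s``; dividing by the peak height gives the area of the
    unit-amplitude transient.
    """
    _validate(rise_s, decay_s)
    return (decay_s - rise_s) / _peak_height(rise_s, decay_s)
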