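"""Seeded synthetic fluorescence-trace generator with known ground truth.

Emulates the recording types the pipeline analyzes:

* agonist recordings — mixtures of non-responding, monotonic and
  oscillatory cells (~10 mHz oscillations), sampled at 5 s or 20 s,
  with exponential photobleaching and additive Gaussian noise;
* store-depletion / calcium re-addition (SOCE) protocol traces;
* dose-response series driven by a four-parameter logistic curve;
* pulse-locked optogenetic stimulation series.

Transients are difference-of-exponentials kernels scaled so the kernel
maximum equals ``amplitude x baseline_level``: amplitudes are fold-change
of baseline, directly comparable to the pipeline's normalized metrics.
Photobleaching is multiplicative on the baseline only; transients ride on
top of the bleached baseline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .kernels import kernel_area, kernel_peak_time, transient_kernel
from .traces import FluorescenceTrace, TraceSet

__all__ = [
    "TraceSimParams",
    "PopulationMix",
    "CellTruth",
    "GroundTruth",
    "simulate_trace",
    "simulate_population",
    "simulate_soce_experiment",
    "simulate_dose_response",
    "simulate_optostim",
]


@dataclass
class TraceSimParams:
    """Shared per-trace simulation parameters.

    ``noise_sd`` is the SD of additive Gaussian noise in units of the
    baseline level (i.e. fold-change units on the normalized scale).
    """

    duration_s: float = 600.0
    frame_interval_s: float = 5.0
    baseline_level: float = 200.0
    bleach_rate: float = 0.0
    noise_sd: float = 0.0
    transient_rise_s: float = 2.0
    transient_decay_s: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.baseline_level <= 0:
            raise ValueError(f"baseline_level must be positive, got {self.baseline_level}")
        if self.bleach_rate < 0 or self.noise_sd < 0:
            raise ValueError("bleach_rate and noise_sd must be non-negative")
        if self.transient_rise_s <= 0 or self.transient_decay_s <= 0:
            raise ValueError("transient time constants must be positive")
        if self.duration_s < 10 * self.frame_interval_s:
            raise ValueError(
                f"duration_s ({self.duration_s}) must cover at least 10 frames"
            )

    @property
    def times(self) -> np.ndarray:
        n = int(np.floor(self.duration_s / self.frame_interval_s)) + 1
        return np.arange(n) * self.frame_interval_s


@dataclass
class PopulationMix:
    """Population composition for agonist-response simulations."""

    n_cells: int = 100
    frac_nonresponder: float = 0.3
    frac_monotonic: float = 0.2
    frac_oscillatory: float = 0.5
    osc_frequency_mHz: float = 10.0
    osc_amplitude: float = 1.0
    response_onset_s: float = 50.0

    def __post_init__(self) -> None:
        if self.n_cells <= 0:
            raise ValueError("n_cells must be positive")
        total = self.frac_nonresponder + self.frac_monotonic + self.frac_oscillatory
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class fractions must sum to 1, got {total}")
        if self.osc_frequency_mHz <= 0:
            raise ValueError("osc_frequency_mHz must be positive")

    @property
    def osc_interval_s(self) -> float:
        return 1000.0 / self.osc_frequency_mHz


@dataclass
class CellTruth:
    """Ground truth for one simulated cell."""

    cell_id: str
    label: str  # nonresponder | monotonic | oscillatory
    peak_times: list[float] = field(default_factory=list)
    amplitudes: list[float] = field(default_factory=list)
    soce_auc: Optional[float] = None

    def __post_init__(self) -> None:
        if self.label == "nonresponder" and self.peak_times:
            raise ValueError("nonresponders must have zero peaks")
        if any(b <= a for a, b in zip(self.peak_times, self.peak_times[1:])):
            raise ValueError("peak times must be strictly increasing")

    @property
    def n_peaks(self) -> int:
        return len(self.peak_times)


@dataclass
class GroundTruth:
    """Per-cell ground truth for a simulated dataset."""

    cells: list[CellTruth]

    def __iter__(self):
        return iter(self.cells)

    def __len__(self) -> int:
        return len(self.cells)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump([asdict(c) for c in self.cells], fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "GroundTruth":
        with open(path) as fh:
            return cls([CellTruth(**d) for d in json.load(fh)])


def _clean_trace(
    params: TraceSimParams, events: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Noise-free trace in raw fluorescence units."""
    t = params.times
    base = params.baseline_level * np.exp(-params.bleach_rate * t)
    out = base.copy()
    for t0, amp in events:
        if amp <= 0:
            raise ValueError(f"event amplitude must be positive, got {amp}")
        if not (0 <= t0 <= params.duration_s):
            raise ValueError(
                f"event time {t0} s outside recording [0, {params.duration_s}] s"
            )
        out = out + amp * params.baseline_level * transient_kernel(
            t - t0, params.transient_rise_s, params.transient_decay_s
        )
    return out


def simulate_trace(
    params: TraceSimParams,
    events: Sequence[tuple[float, float]] = (),
    cell_id: str = "cell_0",
    label: Optional[str] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[FluorescenceTrace, CellTruth]:
    """Simulate one trace from a list of ``(time_s, amplitude)`` events.

    Ground-truth peak times are the event times shifted by the kernel's
    rise-to-peak delay, i.e. where the noise-free trace actually peaks.
    """
    if rng is None:
        rng = np.random.default_rng(params.seed)
    values = _clean_trace(params, events)
    if params.noise_sd > 0:
        values = values + rng.normal(
            0.0, params.noise_sd * params.baseline_level, size=values.shape
        )
    if label is None:
        label = "nonresponder" if not events else (
            "oscillatory" if len(events) >= 2 else "monotonic"
        )
    tp = kernel_peak_time(params.transient_rise_s, params.transient_decay_s)
    truth = CellTruth(
        cell_id=cell_id,
        label=label,
        peak_times=[t0 + tp for t0, _ in events],
        amplitudes=[a for _, a in events],
    )
    trace = FluorescenceTrace(
        cell_id=cell_id,
        times=params.times,
        values=values,
        frame_interval_s=params.frame_interval_s,
    )
    return trace, truth


def _oscillatory_events(
    mix: PopulationMix, duration_s: float
) -> list[tuple[float, float]]:
    times = np.arange(mix.response_onset_s, duration_s + 1e-9, mix.osc_interval_s)
    return [(float(t), mix.osc_amplitude) for t in times]


def simulate_population(
    mix: PopulationMix, params: TraceSimParams
) -> tuple[TraceSet, GroundTruth]:
    """Simulate a seeded mixed population of agonist responses.

    Class labels are drawn per cell from the mix fractions. Oscillatory
    cells receive periodic events every ``1000 / osc_frequency_mHz`` seconds
    from ``response_onset_s``; monotonic cells one event at onset;
    nonresponders none.
    """
    rng = np.random.default_rng(params.seed)
    labels = rng.choice(
        ["nonresponder", "monotonic", "oscillatory"],
        size=mix.n_cells,
        p=[mix.frac_nonresponder, mix.frac_monotonic, mix.frac_oscillatory],
    )
    osc_events = _oscillatory_events(mix, params.duration_s)
    traces, truths = [], []
    for i, label in enumerate(labels):
        if label == "oscillatory":
            events = osc_events
        elif label == "monotonic":
            events = [(mix.response_onset_s, mix.osc_amplitude)]
        else:
            events = []
        trace, truth = simulate_trace(
            params, events, cell_id=f"cell_{i:04d}", label=str(label), rng=rng
        )
        traces.append(trace)
        truths.append(truth)
    return (
        TraceSet(traces=traces, frame_interval_s=params.frame_interval_s),
        GroundTruth(truths),
    )


def simulate_soce_experiment(
    params: TraceSimParams,
    n_cells: int = 50,
    drug_time_s: float = 90.0,
    readd_time_s: float = 690.0,
    depletion_amplitude: float = 1.0,
    soce_amplitude: float = 1.0,
    antagonist_scale: float = 1.0,
    frac_nondepleting: float = 0.1,
) -> tuple[TraceSet, GroundTruth]:
    """Simulate a calcium-free store-depletion / re-addition experiment.

    Each depleting cell shows an ER-release transient at ``drug_time_s``
    and an influx transient of ``soce_amplitude * antagonist_scale`` at
    ``readd_time_s``; ``antagonist_scale`` emulates CRAC-channel blockers
    (1.0 control, ~0.04 for near-complete inhibition). A fraction of cells
    are non-depleting (no transients) to exercise the exclusion rule.
    """
    if not (0 <= drug_time_s < readd_time_s < params.duration_s):
        raise ValueError("require drug_time_s < readd_time_s < duration_s")
    if depletion_amplitude < 0 or soce_amplitude < 0 or antagonist_scale < 0:
        raise ValueError("amplitudes and antagonist_scale must be non-negative")
    rng = np.random.default_rng(params.seed)
    depleting = rng.random(n_cells) >= frac_nondepleting
    scaled_soce = soce_amplitude * antagonist_scale
    area = kernel_area(params.transient_rise_s, params.transient_decay_s)
    traces, truths = [], []
    for i in range(n_cells):
        events: list[tuple[float, float]] = []
        if depleting[i]:
            events.append((drug_time_s, depletion_amplitude))
            if scaled_soce > 0:
                events.append((readd_time_s, scaled_soce))
        trace, truth = simulate_trace(
            params,
            events,
            cell_id=f"cell_{i:04d}",
            label="monotonic" if depleting[i] else "nonresponder",
            rng=rng,
        )
        truth.soce_auc = scaled_soce * area if depleting[i] else 0.0
        traces.append(trace)
        truths.append(truth)
    return (
        TraceSet(traces=traces, frame_interval_s=params.frame_interval_s),
        GroundTruth(truths),
    )


def simulate_dose_response(
    fourpl,
    doses: Sequence[float],
    n_cells_per_dose: int = 200,
    noise_sd: float = 0.2,
    seed: int = 0,
    responder_bottom: float = 0.02,
    responder_top: float = 0.70,
) -> pd.DataFrame:
    """Simulate a per-cell log10-AUC dose-response table from a 4PL curve.

    Per-cell log10 AUC = 4PL(dose) + Gaussian noise. Each cell's responder
    flag is Bernoulli with probability following a second 4PL sharing the
    EC50 and Hill slope. Returns a long table with columns
    ``dose_molar, cell_id, log10_auc, responsive``.
    """
    from .dose_response import four_pl  # local import to avoid cycle

    doses = np.asarray(list(doses), dtype=float)
    if doses.size == 0:
        raise ValueError("dose list must not be empty")
    if np.any(doses <= 0):
        raise ValueError("doses must be positive (molar)")
    rng = np.random.default_rng(seed)
    rows = []
    for d in doses:
        mean = four_pl(
            np.log10(d), fourpl.bottom, fourpl.top, fourpl.log10_ec50, fourpl.hill
        )
        p_resp = four_pl(
            np.log10(d), responder_bottom, responder_top, fourpl.log10_ec50, fourpl.hill
        )
        vals = mean + rng.normal(0.0, noise_sd, size=n_cells_per_dose)
        resp = rng.random(n_cells_per_dose) < p_resp
        for j in range(n_cells_per_dose):
            rows.append(
                {
                    "dose_molar": d,
                    "cell_id": f"d{d:.3e}_c{j:03d}",
                    "log10_auc": vals[j],
                    "responsive": bool(resp[j]),
                }
            )
    return pd.DataFrame(rows)


def simulate_optostim(
    protocol,
    params: TraceSimParams,
    n_cells: int = 50,
    response_prob: float = 1.0,
    per_pulse_amplitude: float = 0.5,
) -> tuple[TraceSet, GroundTruth]:
    """Simulate pulse-locked optogenetic stimulation traces.

    Responding cells (Bernoulli ``response_prob``) receive one transient per
    light pulse; all cells carry the baseline/bleach drift. ``protocol`` is a
    :class:`calosc.optostim.StimProtocol`.
    """
    if not (0 <= response_prob <= 1):
        raise ValueError("response_prob must be in [0, 1]")
    pulse_times = np.asarray(protocol.pulse_times, dtype=float)
    if pulse_times.size and pulse_times[-1] > params.duration_s:
        raise ValueError("protocol pulses extend beyond the recording")
    rng = np.random.default_rng(params.seed)
    responding = rng.random(n_cells) < response_prob
    traces, truths = [], []
    for i in range(n_cells):
        events = (
            [(float(t), per_pulse_amplitude) for t in pulse_times]
            if responding[i]
            else []
        )
        trace, truth = simulate_trace(
            params, events, cell_id=f"cell_{i:04d}", rng=rng
        )
        traces.append(trace)
        truths.append(truth)
    return (
        TraceSet(traces=traces, frame_interval_s=params.frame_interval_s),
        GroundTruth(truths),
    )
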