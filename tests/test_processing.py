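"""Normalization, loess smoothing, extrema detection and peak calling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from calosc.processing import (
    call_peaks,
    find_local_extrema,
    loess,
    normalize_to_baseline,
    process_trace,
    smooth_trace,
)
from calosc.simulate import PopulationMix, TraceSimParams, simulate_population
from calosc.traces import FluorescenceTrace

from conftest import make_norm


def brute_force_extrema(smoothed, frame_interval_s, window_s):
    """Exhaustive per-frame window scan, written independently of the
    filter-based implementation: a frame is a maximum iff it is >= every
    other value within +/- window_s/2 s, exceeds at least one, and no
    earlier frame in the window ties it; minima symmetric."""
    s = np.asarray(smoothed, dtype=float)
    n = len(s)
    half = int(np.floor(window_s / 2 / frame_interval_s + 1e-9))
    maxima, minima = [], []
    for i in range(n):
        lo, hi = max(0, i - half), min(n - 1, i + half)
        is_max = is_min = True
        beats_some_max = beats_some_min = False
        tied_earlier = False
        for j in range(lo, hi + 1):
            if j == i:
                continue
            if s[j] > s[i]:
                is_max = False
            elif s[j] < s[i]:
                beats_some_max = True
            if s[j] < s[i]:
                is_min = False
            elif s[j] > s[i]:
                beats_some_min = True
            if j < i and s[j] == s[i]:
                tied_earlier = True
        if is_max and beats_some_max and not tied_earlier:
            maxima.append(i)
        if is_min and beats_some_min and not tied_earlier:
            minima.append(i)
    return minima, maxima


def merge_alternating_oracle(s, minima, maxima):
    tagged = sorted([(i, "min") for i in minima] + [(i, "max") for i in maxima])
    kept = []
    for idx, kind in tagged:
        if kept and kept[-1][1] == kind:
            prev = kept[-1][0]
            if (kind == "max" and s[idx] > s[prev]) or (
                kind == "min" and s[idx] < s[prev]
            ):
                kept[-1] = (idx, kind)
        else:
            kept.append((idx, kind))
    return (
        [i for i, k in kept if k == "min"],
        [i for i, k in kept if k == "max"],
    )


class TestNormalize:
    def test_constant_trace(self):
        tr = FluorescenceTrace("c", np.arange(12) * 5.0, np.full(12, 200.0), 5.0)
        norm = normalize_to_baseline(tr, baseline_n_frames=5, stimulus_frame=5)
        assert norm.f0 == 200.0
        np.testing.assert_allclose(norm.norm_values, 1.0)

    def test_step_trace_arithmetic(self):
        values = [100.0] * 5 + [150.0] + [100.0] * 6
        tr = FluorescenceTrace("c", np.arange(12) * 5.0, np.array(values), 5.0)
        norm = normalize_to_baseline(tr, baseline_n_frames=5, stimulus_frame=5)
        assert norm.f0 == 100.0
        assert norm.norm_values[5] == 1.5

    def test_noise_free_round_trip_to_ground_truth(self, quiet_params, osc_mix):
        """Normalized trace equals the injected fold-change curve."""
        from calosc.kernels import transient_kernel

        ts, truth = simulate_population(osc_mix, quiet_params)
        tr = ts.traces[0]
        norm = normalize_to_baseline(tr, 10, stimulus_frame=10)
        expected = np.ones_like(tr.times)
        for t0 in np.arange(50.0, 600.0 + 1e-9, 100.0):
            expected += transient_kernel(tr.times - t0, 2.0, 20.0)
        np.testing.assert_allclose(norm.norm_values, expected, atol=1e-9)

    def test_stimulus_before_baseline_rejected(self):
        tr = FluorescenceTrace("c", np.arange(12) * 5.0, np.full(12, 1.0), 5.0)
        with pytest.raises(ValueError, match="baseline"):
            normalize_to_baseline(tr, baseline_n_frames=8, stimulus_frame=5)

    def test_nonpositive_f0_rejected(self):
        tr = FluorescenceTrace("c", np.arange(12) * 5.0, np.zeros(12), 5.0)
        with pytest.raises(ValueError, match="F0"):
            normalize_to_baseline(tr, 5, 5)


class TestLoess:
    def test_constant_preserved(self):
        norm = make_norm(np.ones(40))
        out = smooth_trace(norm, span_s=30.0)
        np.testing.assert_allclose(out.smoothed_values, 1.0, atol=1e-9)

    def test_linear_ramp_preserved(self):
        x = np.arange(40) * 5.0
        norm = make_norm(1.0 + 0.01 * x)
        out = smooth_trace(norm, span_s=30.0)
        np.testing.assert_allclose(out.smoothed_values, 1.0 + 0.01 * x, atol=1e-6)

    def test_noise_reduction_on_sinusoid(self):
        rng = np.random.default_rng(0)
        t = np.arange(120) * 5.0
        clean = 1.0 + 0.5 * np.sin(2 * np.pi * 0.01 * t)
        noisy = clean + rng.normal(0, 0.05, t.size)
        smoothed = loess(t, noisy, span_frac=30.0 / t[-1])
        rmse_raw = np.sqrt(np.mean((noisy - clean) ** 2))
        rmse_smooth = np.sqrt(np.mean((smoothed - clean) ** 2))
        assert rmse_smooth < rmse_raw

    def test_span_exceeding_duration_rejected(self):
        norm = make_norm(np.ones(20))
        with pytest.raises(ValueError, match="exceeds"):
            smooth_trace(norm, span_s=1000.0)

    def test_span_below_two_frames_rejected(self):
        norm = make_norm(np.ones(20))
        with pytest.raises(ValueError, match="two frame"):
            smooth_trace(norm, span_s=5.0)


class TestExtrema:
    def test_monotone_trace_endpoints(self):
        norm = make_norm(np.linspace(1.0, 2.0, 30))
        ex = find_local_extrema(norm, window_s=16.0)
        assert list(ex.minima_indices) == [0]
        assert list(ex.maxima_indices) == [29]

    def test_sinusoid_matches_brute_force(self):
        # 10 mHz sine sampled at 5 s, ending mid-fall at 560 s
        t = np.arange(113) * 5.0
        s = 1.0 + 0.5 * np.sin(2 * np.pi * 0.01 * t)
        norm = make_norm(s)
        ex = find_local_extrema(norm, window_s=16.0)
        assert len(ex.maxima_indices) == 6
        assert len(ex.minima_indices) in (6, 7)
        mn, mx = brute_force_extrema(s, 5.0, 16.0)
        mn, mx = merge_alternating_oracle(s, mn, mx)
        assert list(ex.maxima_indices) == mx
        assert list(ex.minima_indices) == mn

    def test_plateau_keeps_earliest_frame(self):
        s = np.array([1.0, 1.2, 1.5, 1.5, 1.5, 1.2, 1.0, 0.9, 0.9, 1.0, 0.95, 0.9])
        norm = make_norm(s)
        ex = find_local_extrema(norm, window_s=16.0)
        assert list(ex.maxima_indices) == [2, 9]
        assert 7 in ex.minima_indices
        # the 0.9/0.9 plateau keeps only its earliest frame
        assert 8 not in ex.minima_indices

    def test_window_below_two_frames_rejected(self):
        norm = make_norm(np.ones(30), frame_interval_s=20.0)
        with pytest.raises(ValueError, match="fewer than 2 frames"):
            find_local_extrema(norm, window_s=16.0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.integers(0, 10_000), st.integers(20, 120))
    def test_random_traces_match_brute_force(self, seed, n):
        """Oracle equivalence on arbitrary smoothed traces (<= 500 frames)."""
        rng = np.random.default_rng(seed)
        s = np.cumsum(rng.normal(0, 0.1, n)) + 1.0
        if seed % 3 == 0:  # exercise ties/plateaus
            s = np.round(s, 1)
        norm = make_norm(s)
        ex = find_local_extrema(norm, window_s=16.0)
        mn, mx = brute_force_extrema(s, 5.0, 16.0)
        mn, mx = merge_alternating_oracle(s, mn, mx)
        assert list(ex.maxima_indices) == mx
        assert list(ex.minima_indices) == mn

    def test_alternation_invariant(self):
        rng = np.random.default_rng(5)
        s = np.cumsum(rng.normal(0, 0.2, 200)) + 2.0
        norm = make_norm(s)
        ex = find_local_extrema(norm, window_s=16.0)
        tagged = sorted(
            [(i, "min") for i in ex.minima_indices]
            + [(i, "max") for i in ex.maxima_indices]
        )
        kinds = [k for _, k in tagged]
        assert all(a != b for a, b in zip(kinds, kinds[1:]))


class TestPeakCalling:
    def _bump(self, peak_value):
        s = np.concatenate([np.ones(8), [1.0 + (peak_value - 1.0) / 2, peak_value],
                            [1.0 + (peak_value - 1.0) / 2], np.ones(8)])
        return make_norm(s)

    def test_threshold_boundary_inclusive(self):
        norm = self._bump(1.35)
        ex = find_local_extrema(norm, window_s=16.0)
        peaks = call_peaks(ex, norm, threshold=0.35)
        assert len(peaks) == 1
        assert peaks[0].amplitude == pytest.approx(0.35)

    def test_below_threshold_not_called(self):
        norm = self._bump(1.34)
        ex = find_local_extrema(norm, window_s=16.0)
        assert call_peaks(ex, norm, threshold=0.35) == []

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(9)
        s = 1.0 + np.abs(np.cumsum(rng.normal(0, 0.15, 150)))
        norm = make_norm(s)
        ex = find_local_extrema(norm, window_s=16.0)
        counts = [len(call_peaks(ex, norm, threshold=th)) for th in
                  [0.1, 0.2, 0.35, 0.5, 1.0]]
        assert counts == sorted(counts, reverse=True)

    def test_simulated_five_event_trace_recovers_peaks(self, quiet_params):
        from calosc.simulate import simulate_trace

        events = [(60.0 + 100 * k, 1.0) for k in range(5)]
        params = TraceSimParams(noise_sd=0.01, seed=4)
        trace, truth = simulate_trace(params, events)
        _, _, peaks = process_trace(trace, stimulus_frame=10)
        assert len(peaks) == 5
        called = np.array([p.peak_time_s for p in peaks])
        np.testing.assert_allclose(
            called, truth.peak_times, atol=params.frame_interval_s
        )

    def test_peak_recovery_sensitivity_precision(self):
        """>= 95% sensitivity and precision at low noise, amplitude >= 0.5."""
        params = TraceSimParams(noise_sd=0.02, seed=21)
        mix = PopulationMix(
            n_cells=40, frac_nonresponder=0.2, frac_monotonic=0.2,
            frac_oscillatory=0.6, osc_amplitude=0.5,
        )
        ts, truth = simulate_population(mix, params)
        tp = fp = fn = 0
        for tr, cell in zip(ts.traces, truth):
            _, _, peaks = process_trace(tr, stimulus_frame=10)
            called = [p.peak_time_s for p in peaks]
            true_times = list(cell.peak_times)
            for t_true in true_times:
                if any(abs(c - t_true) <= 2 * params.frame_interval_s for c in called):
                    tp += 1
                else:
                    fn += 1
            for c in called:
                if not any(abs(c - t_true) <= 2 * params.frame_interval_s for t_true in true_times):
                    fp += 1
        sensitivity = tp / (tp + fn)
        precision = tp / (tp + fp)
        assert sensitivity >= 0.95
        assert precision >= 0.95


class TestScaleInvariance:
    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(st.floats(0.01, 1000.0))
    def test_raw_scaling_leaves_pipeline_unchanged(self, c):
        params = TraceSimParams(noise_sd=0.02, seed=13)
        from calosc.simulate import simulate_trace

        trace, _ = simulate_trace(params, [(100.0, 1.0), (250.0, 0.8)])
        scaled = FluorescenceTrace(
            trace.cell_id, trace.times, trace.values * c, trace.frame_interval_s
        )
        n1, e1, p1 = process_trace(trace, stimulus_frame=10)
        n2, e2, p2 = process_trace(scaled, stimulus_frame=10)
        np.testing.assert_allclose(n2.norm_values, n1.norm_values, rtol=1e-9)
        assert list(e1.maxima_indices) == list(e2.maxima_indices)
        assert [p.peak_index for p in p1] == [p.peak_index for p in p2]
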