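import numpy as np
import pytest

from calosc.simulate import PopulationMix, TraceSimParams
from calosc.traces import NormalizedTrace


@pytest.fixture
def quiet_params():
    """Noise-free 600 s recording at 5 s frames."""
    return TraceSimParams(
        duration_s=600.0,
        frame_interval_s=5.0,
        baseline_level=200.0,
        noise_sd=0.0,
        seed=0,
    )


@pytest.fixture
def osc_mix():
    """All-oscillatory population at 10 mHz, onset 50 s."""
    return PopulationMix(
        n_cells=10,
        frac_nonresponder=0.0,
        frac_monotonic=0.0,
        frac_oscillatory=1.0,
        osc_frequency_mHz=10.0,
        osc_amplitude=1.0,
        response_onset_s=50.0,
    )


def make_norm(values, frame_interval_s=5.0, smoothed=None, cell_id="c0"):
    """Build a NormalizedTrace directly from (already normalized) values."""
    values = np.asarray(values, dtype=float)
    times = np.arange(len(values)) * frame_interval_s
    return NormalizedTrace(
        cell_id=cell_id,
        times=times,
        norm_values=values,
        f0=1.0,
        baseline_window=(0, min(5, len(values))),
        frame_interval_s=frame_interval_s,
        smoothed_values=np.asarray(smoothed, dtype=float) if smoothed is not None else values.copy(),
    )
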