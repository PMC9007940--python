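# Methods

## Trace model and normalization

A recording is a set of per-cell ROI intensity traces on a shared uniform
time grid (frame interval 5 s for short agonist/SOCE recordings, 20 s for
hours-long optogenetic recordings). Raw intensities are arbitrary units;
all analysis happens on the F/F₀ scale, where F₀ is the mean of a block of
frames immediately preceding the stimulus (default 10 frames; the
convention allows 5–10 and more frames lower the variance of F₀). F₀ ≤ 0
or a stimulus frame earlier than the baseline block is a hard error. All
downstream quantities are scale-invariant: multiplying a raw trace by any
positive constant leaves normalized values, extrema, and peak calls
unchanged (tested).

## Loess smoothing

Peak detection runs on a loess-smoothed copy of the normalized trace:
locally weighted quadratic regression with tricube weights over the k
nearest frames, k set by a span expressed in seconds (default 30 s,
converted to a fraction of trace length). Degree-2 local fits reproduce
constants and straight lines exactly and track curvature at peaks better
than local-linear smoothers. Endpoints are fitted with the same local
regression over a one-sided neighborhood. The default span is a
compromise: wide enough to suppress frame-to-frame noise, well below the
~100 s period of the oscillations it must preserve. The span must be at
least two frame intervals and at most the trace duration. Whether robust
re-weighting iterations should be applied is an open convention; none are
used here (plain weighted least squares).

## Extrema and peak calling

Local extrema are found in centered sliding windows of 16 s (±8 s,
truncated at the trace edges; at 5-s sampling this is ±1 frame). Frame i
is a maximum iff its smoothed value is ≥ every other value in its window,
strictly exceeds at least one of them, and no earlier frame in the window
ties it — so a flat plateau contributes at most one extremum, at its
earliest frame, and a fully constant trace contributes none. Minima are
symmetric. Runs of same-type extrema are merged (keeping the more extreme
value, earliest on ties) so minima and maxima alternate. The
implementation is checked against an exhaustive per-frame scan written
independently in the test suite.

A calcium peak is a maximum whose smoothed amplitude above the preceding
local minimum is ≥ 0.35 fold-change; the comparison is inclusive (the
boundary amplitude 0.35 is called, 0.34 is not). A maximum with no
preceding minimum is referenced to the first frame. A window covering
fewer than 2 frames (e.g. 16 s at 20-s sampling) is an error rather than a
silently degenerate scan.

## Per-cell metrics

Responsive = ≥ 1 peak; oscillatory = ≥ 2 peaks. Duration runs from the
minimum preceding the first peak to the minimum following the last peak,
or to the recording end when the last response is on-going. Frequency
(defined only for oscillatory cells) is `n_peaks / duration`, reported in
mHz, so frequency × duration recovers the peak count exactly. AUC is the
trapezoidal integral of (F/F₀ − 1) over the same span, with negative
excursions included as-is; the baseline is F₀ (norm = 1), not the local
pre-peak value. Zero-peak cells carry AUC 0 by convention and are excluded
from AUC summaries. AUC and frequency are log₁₀-transformed for
population statistics (their raw distributions are right-skewed;
non-positive values are dropped with a warning count). Peak amplitude is
measured on the smoothed trace, consistent with peak identification.

Condition summaries report % responsive, % oscillatory among responsive,
mean amplitude/duration/log₁₀ AUC/frequency. With replicate labels, each
metric is averaged within replicates first and the SEM is taken across
replicate means (biological-replicate hierarchy); a single replicate has
no SEM. Without labels, statistics are across cells.

## SOCE assay

F₀ for SOCE traces is the mean of frames before drug addition. Inclusion
requires the smoothed trace to reach 1.35 (≥ 0.35 fold-change) anywhere
between drug addition and calcium re-addition; raising the threshold can
only shrink the included set (tested). ER-depletion AUC/amplitude use a
fixed window after drug addition (default 600 s) that must end by
re-addition, so influx can never leak into depletion metrics. SOCE
AUC/amplitude use a fixed window after re-addition (default 480 s);
comparing conditions with unequal SOCE windows is a hard error, and a
window past the recording end is truncated with a warning. At zero noise
the SOCE AUC is exactly linear in the injected influx amplitude.
Condition-level normalization divides each replicate's mean SOCE AUC by
the mean ER-release AUC of that replicate's control cells; a missing
matched control is an error.

## Dose–response fitting

The 4PL model is fitted by bounded least squares (scipy `curve_fit`,
trust-region reflective) on the log₁₀-dose axis, to per-dose mean log₁₀
AUC (the per-dose-mean convention matches how such curves are plotted as
mean ± SEM). Initialization: bottom/top from the min/max of the dose
means, log₁₀ EC₅₀ from the dose nearest half-maximum, Hill slope 1;
the Hill slope is bounded to [0.1, 10] to prevent divergence on flat
data. Zero doses are excluded from the log-axis fit (log undefined) but
may inform the bottom initialization. Fewer than 4 distinct positive
doses or an all-constant response is an error; optimizer non-convergence
is flagged on the returned fit and warned about, never silently returned.
Rescaling dose units shifts log₁₀ EC₅₀ by exactly the unit factor and
leaves the other parameters unchanged.

## Rubberband baseline and optogenetic analysis

Long recordings drift (photobleaching, focus); the baseline is the
greatest convex minorant of the (time, value) points — the "rubberband"
stretched under the trace — computed with Andrew's monotone-chain lower
hull and evaluated at every frame by linear interpolation between hull
vertices. It is parameter-free, deterministic, convex, never exceeds the
trace, and is checked against an O(n²) gift-wrapping oracle in the tests.
Spline refinement of the hull is deliberately omitted.

Responsiveness uses *division* normalization (trace / baseline, a
fold-of-baseline scale shared with F/F₀ metrics): a cell is responsive if
the loess-fitted normalized trace rises ≥ 12.5% above baseline within
2 min of the first light pulse. Total stimulated flux uses *subtraction*
normalization: AUC of (trace − baseline) from the first pulse to the
recording end. Both normalizations are kept distinct on purpose.

Protocols are defined by pulse interval, pulse duration, baseline period
and total duration; pulses run from the end of the baseline period to the
end of the recording. Frequency is 1000/interval in mHz; the reported
label truncates to two decimals (1/1800 s → 0.55 mHz). Exposure matching
computes the pulse duration that gives a second interval exactly the same
duty cycle (330 ms at 300 s → 1980 ms at 1800 s; the 2000 ms used in
practice is a ~1% rounding of this).

## Synthetic-data generator

The generator renders each trace as
`baseline_level · exp(−bleach_rate·t) + Σ transients + noise`, with
transients shaped by a difference-of-exponentials kernel
`exp(−t/τ_decay) − exp(−t/τ_rise)` normalized to unit maximum and scaled
by `amplitude × baseline_level`, so amplitudes are fold-change of baseline
and directly comparable to pipeline outputs. Defaults: τ_rise 2 s,
τ_decay 20 s (fast-rise/slow-decay GCaMP6s-like shape), baseline 200,
noise SD in fold-change units. The kernel has closed-form peak time and
area, used as analytic oracles. Bleaching is multiplicative on the
baseline only, which makes drift-only traces exactly correctable by the
rubberband baseline. Ground truth records each cell's class, true peak
times (event time + kernel rise-to-peak delay) and amplitudes; noise-free
traces are exactly reconstructible from it, and identical seeds give
bitwise-identical datasets.

Population defaults emulate a strongly-responding agonist condition:
30% non-responders / 20% monotonic / 50% oscillatory, oscillation
frequency 10 mHz (one event per 100 s) from a 50-s onset, amplitude 1.0
fold-change. Class labels are drawn per cell, so realized counts are
binomial around the requested fractions. The SOCE simulator injects one
depletion transient at drug time and one influx transient at re-addition,
scales influx by an antagonist factor (1.0 control, ~0.04 for
near-complete CRAC blockade), and makes 10% of cells non-depleting by
default to exercise the exclusion rule. The dose–response simulator draws
per-cell log₁₀ AUC as 4PL(dose) + Gaussian noise (SD 0.2 by default) and
responder flags from a second 4PL sharing EC₅₀ and Hill slope (bottom 2%,
top 70%, matching the plateau of realistic %-responding curves); the
ground-truth 4PL for log₁₀ AUC uses bottom 1.0 and top 2.5, consistent
with full-response AUCs of a few hundred unit·seconds. The optogenetic
simulator gives each responding cell (Bernoulli probability) one transient
per light pulse.

What the generator does **not** emulate: indicator saturation and
nonlinearity, trial-to-trial kinetic variability, correlated (shot +
motion) noise, cell-to-cell baseline heterogeneity within a trace set,
irregular oscillation intervals, and segmentation/tracking artifacts.
Passing tests therefore demonstrate correctness of the measurement
pipeline under known ground truth, not robustness to every property of
real recordings.

## Numerical and design notes

- Peak/depletion thresholds are inclusive (≥); the boundary behavior is
  pinned by tests.
- Integrals are trapezoidal on the sampled grid. Kernel-integral checks
  use kinetics resolvable at the grid spacing (e.g. 1-s frames for the
  2 s/20 s kernel), since a 2-s rise sampled at 20 s is under-resolved by
  any quadrature.
- Frequency recovery on the default oscillatory design reads ~10.8 mHz
  for a 10 mHz event train: the duration denominator (pre-first-peak
  minimum to post-last-peak minimum, ~550 s) is shorter than
  `n_peaks × interval` (600 s). This is a property of the
  count-over-duration estimator itself, not an implementation artifact.
- Plateau tie-breaks keep the earliest frame; merged same-type extrema
  keep the more extreme value, earliest on ties.
- Problem sizes in tests and the acceptance script (100-cell populations,
  200 cells/dose, ≤ 300-frame oracle comparisons) are chosen so every
  check runs in seconds while keeping binomial/fit uncertainties well
  inside the asserted tolerances.

## Known limitations

- The loess smoother is O(n·k) per trace; adequate for hundreds-to-
  thousands of frames, not optimized for very long recordings.
- No spike deconvolution, rolling-percentile ΔF/F baselines, confidence
  intervals on EC₅₀ (profile likelihood), or formal hypothesis testing —
  per-cell and per-condition tables are exported for external statistics.
- The rubberband baseline assumes drift is convex-correctable; oscillatory
  drift (e.g. periodic focus breathing) is not removed.
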