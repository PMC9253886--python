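# Methods

This note records the models, parameter choices and numerical decisions
behind `lfprhythms`, and what the synthetic validation does and does not
establish.

## Signal model and filtering

All band-limited quantities derive from linear-phase FIR bandpass filters
(Hamming-windowed sinc). The tap count follows
`n = max(401, int(50 / (22 · (HF − LF) / SR)))` — the classical Hamming
design rule with 50 dB stopband attenuation over a transition proportional
to the bandwidth — floored at 401 coefficients and forced odd (Type I) so
the integer group delay can be removed exactly. Filtering reflect-pads the
series by one filter length before convolution, so passband components come
out amplitude- and phase-aligned with the input (cross-correlation peak at
lag 0); the suite asserts linearity and a stopband rejection below 1% for
a tone 3 Hz outside the θ passband at 512 samples/s.

Default band edges (Hz): δ 0.5–4, θ 5–12, γ 30–120, ripple 120–250,
spindle 10–30. Instantaneous amplitude and phase come from the Hilbert
analytic signal; the phase of cos(2πft) is 0 at its peaks.

## Vigilance staging

Per-second RMS(γ)/RMS(δ) ratios (8 s windows, 1 s steps) are histogrammed
(200 equal-width bins over the 0.1–99.9 percentile range) and fit with a
sum of two Gaussians by nonlinear least squares. The fit is multi-started
(quartile-, tail-percentile- and two-cluster-k-means-based initializations
plus the two most prominent histogram modes); among converged candidates
the one with the highest data log-likelihood of its implied mixture is
kept. Likelihood selection matters: a pure histogram-residual criterion
happily spends both Gaussians on substructure of the dominant (skewed) NREM
mode while leaving the broad minority AWAKE mode unexplained, whereas the
likelihood of the raw values penalizes that heavily. A fit is flagged
unidentifiable when the component means coincide (separation below half
the wider SD) or one component carries under 2% of the mass.

NREM membership probabilities use the published step constants 1, 0.397
and 0.067 at 1, 2 and 3 SD above the low component's mean (0 beyond 3 SD);
these constants are used verbatim, not recomputed from normal tables. A
second is NREM when at least one flanking 8 s window averages probability
≥ 0.5 (the contrapositive of the both-flanks-below exclusion rule),
truncated at block edges.

Outside NREM, the θ/δ ratio histogram is fit the same way and the REM/AWAKE
threshold is the density-equality point between the two means (closed-form
quadratic in the log densities; when no root lies between the means, a
density-weighted midpoint is used and flagged). A candidate REM run must
touch an NREM run on at least one side; because the 8 s RMS epochs smear
state transitions, up to 2 sub-threshold transition seconds between the
NREM run and the candidate run still count as adjacency and are absorbed
into the REM run — without this, the ratio ramp at NREM→REM transitions
strands genuine REM behind a 1–2 s AWAKE sliver. All threshold comparisons
are strict. Activity-based reclassification runs in three ordered passes:
REM seconds with activity above the pooled REM∪AWAKE median become AWAKE;
AWAKE seconds with activity below the NREM median become REM; REM runs
immediately preceded by an AWAKE second become AWAKE. The pooled (not
per-state) median is used in pass 1.

## Whitened spectral peaks

Per 8 s window (1 s steps; 0.125 Hz resolution), the Hann-tapered FFT
power is smoothed inside the band with a 5-point moving average — the power
itself, not its log, since deep chi-squared nulls would bias a log-domain
baseline low. The baseline is the straight line in log f – log P space
through the two band-edge values, each estimated from a 15-bin neighbourhood
of its edge (capped at a third of the band) so a single noisy edge bin
cannot tilt the line. The peak is the largest positive residual; it counts
as significant only if it exceeds both 2× the median absolute in-band
residual and 5 robust SDs (1.4826·MAD) above the residual median. The
second term controls the per-window false-alarm rate: on pure 1/f^α noise
the residual maximum routinely clears the median-based floor alone
(measured false-alarm 0/200 windows with both terms; detected peaks land
within ±0.125 Hz of an inserted tone at in-band SNR ≥ 2).

Windows are assigned to the majority vigilance state of their seconds
(ties to the earlier second's state); hourly means per state feed a
fixed-period 24 h sinusoid fit m + a·sin(2πt/24 + φ), which is linear in
(m, a cos φ, a sin φ) and therefore exact; fewer than 48 finite hourly
values raises a wide-uncertainty flag. Light/dark comparisons use the
two-sample KS test at α = 0.001 (all other tests use 0.05).

## Cross-frequency coupling

The modulation index bins γ amplitude by θ phase (18 bins of π/9; phase 0
at the θ peak), normalizes the bin means to a distribution and reports
KL(P‖uniform)/log N ∈ [0, 1]; empty bins are dropped with N reduced
accordingly. γ rows span 30–120 Hz in 10 Hz bins — 9 non-overlapping bins
by default; a 14-bin overlapping scheme (10 Hz wide, evenly spaced starts)
is selectable and every matrix records its scheme. PAC method 1 delimits θ
cycles trough-to-trough from the analytic phase and takes per-segment
peak-to-peak γ amplitude medians; method 2 histograms continuous Hilbert γ
amplitude over continuous θ phase. Both require at least 10 epochs.
Averaged matrices are Z-scored over cells and spline-upsampled (order-3)
for display only; coordinates of maximal coupling always come from the
non-Z-scored average (ties resolve to the lowest γ bin and earliest
column, flagged). "Significant" coupling is judged against 200 circular
time-shift shuffles of the amplitude series (95th percentile).

On synthetic data with the γ envelope (1 + d·cos(φ_θ − φ₀))/(1 + d), both
methods recover φ₀ to well within one phase bin (π/9) at depth d ≥ 0.3,
and agree with each other within one bin.

## Inter-site δ synchrony

ISPC is the modulus of the mean unit phasor of the phase differences; it is
1 for any constant offset and has null expectation √(π/(4n)) for
independent phases (checked by Monte-Carlo at n = 10², 10³, 10⁴). Sliding
ISPC defaults to 2 s windows stepped by 0.1 s. Phase-difference histograms
use 72 bins of π/36 over (−π, π] with a single-Gaussian least-squares fit
initialized from the circular moments; a fit residual above 25% of the peak
count flags bimodality. The compound frequency is the mean of the two
sites' mean instantaneous frequencies (endpoint difference of the unwrapped
phase), and the lag is Δφ/(2πf)·1000 ms.

## Event detection

Both detectors share one construction: FIR bandpass, rectification
(square then square-root), a short moving-RMS envelope, and z-scoring
against the NREM baseline (mean/SD over NREM samples, re-estimated once
with detected events excluded). Ripples: threshold z ≥ 3, boundaries
extended to the z = 0 return points, envelope smoothing 6 ms, and a 10 ms
minimum supra-threshold core. The smoothing window sets the envelope
correlation time and hence how far the z = 0 boundary extension wanders
through noise — 6 ms keeps detected onsets within ±25 ms of truth; the
10 ms core requirement culls single-sample noise excursions that the bare
z ≥ 3 crossing rule admits. Spindles: threshold 5 SD, 5 ms minimum
supra-threshold duration (kept as published, configurable — conventional
floors are an order of magnitude longer), 30 ms envelope smoothing and a
100 ms merge gap suited to multi-cycle events. Per-event peak frequency is
the dominant component of the zero-padded FFT of the band-passed event.
Sharp-wave placement is validated by comparing the raw-trace event mean
with both flanking equal-duration baselines (pass iff within 1 SD of each;
single-flank at recording edges, flagged).

Ripple→spindle coupling reports, for every ripple, the latency to the next
spindle onset and the fraction followed within a configurable window
(default 5 s, stated with every summary). Note that with a 5 s window the
followed fraction includes a chance term 1 − exp(−λ_spindle·5) from
unrelated spindles; validation against the configured coupling probability
therefore uses sparse trains or a chance-corrected oracle. Burstiness
B = (σ−μ)/(σ+μ) of the IEIs and memory M = corr(IEIᵢ, IEIᵢ₊₁) follow the
Goh–Barabási definitions: B = −1 for perfectly regular trains, 0 for
Poisson, positive for bursty; M is 0 (flagged) when undefined.

## Statistics

Cohen's d uses the root-mean of the two group variances,
|M₁−M₂|/√((SD₁²+SD₂²)/2), with the anchor scale small ≤ 0.2, medium 0.5,
large 0.8, very large ≥ 1.2; interval labels switch at the midpoints
between anchors (0.35, 0.65, 1.2) and the raw d is always reported
alongside. Rank tests delegate to scipy with exact null distributions when
the combined sample size is at most 25 and ties permit, tie-corrected
normal approximations otherwise; all p-values are two-tailed. The
Dunn–Holland–Wolfe multiple comparison ranks all observations jointly,
compares each pair's mean-rank difference with
SE = √((N(N+1)/12 − T/(12(N−1)))·(1/nᵢ + 1/nⱼ)) (tie term T = Σ(t³−t)),
applies a Bonferroni family-wise factor over the k(k−1)/2 pairs, and
refuses to run without a significant Kruskal–Wallis omnibus (for two
groups it reduces to the Wilcoxon–Mann–Whitney decision). Simulated
family-wise type-I error under the null is within binomial tolerance of
0.05.

## The synthetic generator

The generator emulates the statistical structure the analyses assume: an
exponential-dwell semi-Markov AWAKE→NREM→(REM)→AWAKE schedule with
photoperiod-dependent dwell means (defaults: AWAKE 240/480 s light/dark,
NREM 360/180 s, REM 60 s, REM entered from NREM with probability 0.6 —
yielding an NREM-dominant light phase and AWAKE-dominant dark phase);
state-dependent band amplitudes (mV: AWAKE δ 0.05 θ 0.07 γ 0.09; NREM
δ 0.14 θ 0.03 γ 0.03; REM δ 0.02 θ 0.13 γ 0.10 — δ chosen to land in the
published sleep-amplitude range) with slow lognormal within-state
fluctuation (log-SD 0.25, ~20 s correlation time; real band power is not
constant within a state, and the ratio-histogram fits assume modes of
finite width); counterphase 24 h sinusoidal carriers (θ 7.5 ± 0.4 Hz,
γ 80 ∓ 5 Hz); γ amplitude modulation (1 + d·cos(φ_θ − φ₀))/(1 + d);
channel-2 δ lagged and jittered (Gaussian jitter of SD σ gives
ISPC = e^(−σ²/2) and trace correlation ≈ e^(−σ²/2), so any target ISPC is
dialled in analytically); 1/f^α background (spectral shaping of white
noise, α = 1, broadband RMS 0.02 mV); and a lognormal activity trace
(high-mean during AWAKE). Ripples are 50 ms Hann-windowed bursts at 180 Hz
on a mean-balanced slow deflection, inserted as a Poisson process
(0.44 s⁻¹) in NREM; spindles are 0.5 s Hann-windowed 15 Hz bursts on
channel 2 — multi-cycle, as real spindles are, rather than the much
shorter supra-threshold durations a detector reports — partly coupled to
ripples (fraction 0.14, gamma-distributed latency 2.0 ± 1.5 s) plus an
independent 0.035 s⁻¹ process. Event amplitudes are SNR multiples of the
composed in-band NREM background (ongoing rhythms plus noise — the
reference a detector actually competes against), defaults 8 (ripples) and
10 (spindles). A fixed seed gives bit-identical output.

What the generator does **not** emulate: volume conduction and reference
artifacts, movement and chewing artifacts, non-sinusoidal θ waveform
asymmetry, state transitions with intermediate electrographic character,
electrode drift, and realistic spindle/ripple waveform diversity.
Passing recovery tests therefore demonstrates correctness of the
implementations under the stated statistical assumptions, not robustness
to every pathology of real recordings.

## Problem sizes

The validation suite runs at 512 samples/s (all analysis parameters derive
from the sample rate; nothing is hard-coded to the 2048 s⁻¹ acquisition
rate). Staging recovery uses one 2 h recording (≥ 90% per-second agreement
with truth, ≥ 95% NREM-vs-rest, measured 0.90–0.97 across seeds);
event-detection recovery uses 10 min of NREM (~250 ripples, ~60 spindles);
PAC recovery uses 12 × 8 s epochs per condition; circadian recovery uses
48 hourly 64 s chunks generated at the corresponding clock hours — the
per-hour chunk stands in for the hour it samples, at reduced duty cycle.

## Known limitations

* The REM/AWAKE split needs at least 1000 non-NREM seconds for a stable
  mixture fit; shorter blocks leave all non-NREM seconds AWAKE (flagged).
* Whitened-peak detection trades sensitivity for a near-zero false-alarm
  rate; weak peaks (in-band SNR ≈ 2) are found in only about half of
  individual 8 s windows, though detected frequencies are always within
  one resolution step. Hourly averages are unaffected.
* Detected event onsets lag slow-rising events (the envelope crosses
  threshold partway up the ramp); for multi-cycle spindles, matching
  against truth is by interval overlap rather than onset distance.
* EDF files can be read (via mne) but not written; the native format is a
  float32 stream with a JSON sidecar.
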