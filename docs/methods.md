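# Methods

This note documents the models, conventions and numerical choices behind
`gammaforge`, the way a pipeline maintainer would want them recorded.

## Scope and data model

The package analyses two families of electrophysiological time series
from hippocampal slice work: extracellular local field potentials (LFPs,
µV, typically 10 kHz) carrying gamma-band (20–80 Hz) oscillations, and
intracellular current recordings (pA) of evoked or spontaneous
postsynaptic currents. The universal container is `Trace` (uniformly
sampled 1-D signal with sampling rate, unit and metadata); evoked trains
are `TrainResponse` tables of per-pulse amplitudes.

Since raw recordings are not redistributable, every input class has a
synthetic generator with exact ground truth, and all quantitative claims
of the test suite are parameter-recovery or analytic-identity statements
about synthetic data.

## Spectral quantification

A spectrum is the average of Hann-windowed periodograms over consecutive
**non-overlapping 4096-sample segments** of the analysis epoch, with
per-segment mean removal (a 60 s epoch at 10 kHz yields 146 segments and
a 2.441 Hz bin width). Power is reported per bin in µV² with the window
correction chosen so that **the sum over all bins equals the
(per-segment detrended) signal variance**; a pure sinusoid of amplitude
A therefore contributes A²/2 regardless of the window. This is what
makes summated band power comparable to analytic values and is enforced
by a Parseval test at 1 %.

Derived metrics, all on bin centres with half-open bands `[low, high)`:

* **summated power** — sum of bin power over 20–80 Hz (oscillation
  strength);
* **peak frequency** — dominant bin in 20–80 Hz, ties resolved to the
  lower frequency, an all-zero band raising `UndefinedPeakError` rather
  than returning 0 Hz;
* **spontaneous-gamma classifier** — true iff mean bin power over
  25–35 Hz *strictly* exceeds that over 10–20 Hz (exact equality →
  false, so the classifier is deterministic on ideal flat spectra).

No software mains notch is applied by default; re-analysis of hardware
that already removed 50/60 Hz noise needs none, and a notch would bite
into the gamma band.

## Gamma-cycle waveform averaging

A 2 s epoch is band-pass filtered at 20–80 Hz with a 2nd-order
Butterworth filter applied forward–backward (zero phase, magnitude
response squared), so cycle peak times are not biased. Candidate cycles
are **positive local maxima of the filtered signal whose height lies
between 30 % and 70 % (inclusive) of the epoch's maximum filtered
value**; this excludes the largest cycles and makes selection invariant
to overall amplitude scaling, which is what allows kinetic comparison
between groups of different oscillation power. At most 50 cycles are
taken in temporal order; fewer than 30 is reported with a warning, never
padded. The raw (unfiltered) trace is averaged in windows centred on the
selected peaks; the default half-window is one period of the epoch's
peak frequency. Normalisation scales the average to unit peak for shape
comparison.

## Cross-channel coherence

For a roving channel against a fixed reference, the Pearson correlation
of the two **band-passed (20–80 Hz)** signals is evaluated at every
integer-sample lag within ±max_lag (raw-signal mode is available by
flag; band-passing is the default because broadband trends bias the
correlogram peak). The peak gives the maximum correlation and its lag;
parabolic interpolation through the three points around the peak is
reported separately as a sub-sample lag. Phase lead = lag × dominant
frequency × 360°/1000, wrapped to (−180°, 180°], positive when the
roving channel peaks after the reference.

## Evoked-train analysis and RRP estimation

Stimulus–response curves are fitted with a 3-parameter logistic
`max/(1+exp(−k(V−h)))` (Boltzmann-equivalent); the slope at half-max is
`k·max/4` analytically. Fits whose half-max falls outside the sampled
intensity range, or whose fitted plateau exceeds the observed maximum by
more than 20 %, are flagged unreliable (non-saturating data). PSP slopes
are least-squares line fits over the 20–80 % amplitude span of the
rising phase; absent responses are reported as missing, never zero.

Train metrics on first-response-normalised amplitudes: the pulse-2
ratio, the mean of pulses 8–10, and the steady state as the mean of the
last five responses in percent.

The **readily releasable pool (RRP)** is estimated from 40-pulse, 20 Hz
trains by cumulative-amplitude back-extrapolation: cumulative amplitude
is regressed on pulse time over the 1–2 s window (inclusive) and the
intercept at t = 0 is the RRP in pA. Pulse i is placed at t =
i/stim_freq (first pulse at 50 ms), so the window covers pulses 20–40;
the alternative origin (first pulse at t = 0) is selectable. Derived
quantities: P_ves = first amplitude / RRP (mean first amplitude across
sweeps when several are supplied) and N_syn = RRP / quantal amplitude,
reported raw and rounded. The quantal amplitude is an explicit input —
the pipeline never assumes a value.

**Known estimator bias.** Back-extrapolation assumes the pool is
essentially exhausted before the fit window, leaving a late phase whose
slope is pure replenishment. With the depletion model below this holds
for release probabilities around 0.25 and above (recovery within ~2 %),
but at P ≈ 0.08 only ~81 % of the pool is spent by t = 1 s, the
cumulative curve is still convex across the window, and the intercept
underestimates the generating pool by roughly a third. The estimator
test suite pins this behaviour against an independent recurrence + OLS
oracle rather than pretending it away; low-P estimates from 2 s trains
should be read as lower bounds. Faster replenishment additionally
inflates the late-phase slope (verified monotone over a τ_rec grid).

## Synthetic generators

* **LFP** — sinusoid of exact amplitude/frequency (variance A²/2 by
  construction) plus Gaussian background, optionally 1/f^β-shaped by
  spectral multiplication and renormalised to the requested total SD.
  Multi-channel variants delay the oscillation by a per-channel lag
  (phase-exact, not sample-rounded) and attenuate it, with independent
  noise per channel; lags ≥ one period trigger a phase-wrap warning.
* **Evoked trains** — mean-field depletion–replenishment recurrence:
  available pool R starts at N; pulse i releases P_i·R_i·q; the pool
  recovers toward N as R ← R_rem + (N−R_rem)(1−exp(−Δt/τ_rec));
  facilitation adds `facilitation_increment` to the release probability
  per pulse and decays with τ_fac, clipped so P_i ≤ 1. Multiplicative
  Gaussian amplitude noise (CV) perturbs measurements only — pool
  dynamics and the GroundTruth released amounts stay exact. Without
  replenishment the cumulative obeys C_i = N·q·(1−(1−P)^i) in closed
  form, which is the main generator oracle. With P = 0.05, increment
  0.02/pulse, τ_fac = 0.3 s and τ_rec = 2 s, a 10-pulse 33 Hz train
  facilitates to a ~147 % plateau, the wild-type-like regime.
* **Spontaneous PSCs** — Poisson event times, Gaussian amplitudes
  (floored at 1 % of the mean), convolved with a unit-peak
  difference-of-exponentials kernel plus white noise. Defaults: rise
  0.5 ms, decay 8 ms (typical whole-cell IPSC kinetics near 32 °C),
  amplitude CV 0.2, rate 12.6 Hz, amplitude 38.3 pA, noise SD 3.8 pA
  (10:1 peak SNR).
* **Stimulus–response** — exact logistic plus optional noise.

All generators draw from one seeded `numpy` Generator per call and echo
their parameters (and latent event times / released amounts / lags) in
an immutable `GroundTruth` sidecar; identical spec + seed is
bit-reproducible.

What the generators deliberately do **not** emulate: biophysical gamma
generation (no interneuron network), stochastic single-vesicle release,
electrode drift, seal instability, overlapping-event kinetics beyond
linear superposition, and non-stationary event rates. Passing tests
therefore demonstrate correctness of the *analysis operations* under
controlled conditions, not robustness to every pathology of real
recordings.

## Event detection

Baseline is the global trace median (robust to event load); polarity is
explicit. Candidates are local maxima of the rectified signal after a
short boxcar smoothing (default 0.5 ms) that exceed the threshold with a
prominence of at least half the threshold — the smoothing + prominence
pair suppresses noise chatter on event decays, which would otherwise
split single PSCs into several detections. Peaks closer than the
refractory interval (default 2 ms) are merged keeping the larger.
Amplitudes are read from the unsmoothed signal at the detected peak;
`baseline="local"` subtracts a per-event pre-event median (10–2 ms
before the peak), removing the upward bias of events riding on earlier
decays. At 12.6 Hz and 10:1 SNR the detector's residual undercount is
~2–3 %, dominated by genuinely unresolvable events closer than the
refractory interval.

## Statistics

Unpaired two-sided t-test (pooled variance by default, Welch by flag)
with per-group Shapiro–Wilk reported alongside — a normality failure is
surfaced, not silently re-routed to a nonparametric test. Bonferroni
correction is `min(1, m·p)` with the family size m a required input.
Repetitive-stimulation experiments use a two-factor (group × pulse)
type-II ANOVA via statsmodels. The harness's type-I error is verified at
0.05 ± 0.02 over 2000 null simulations, and its power against a
7-vs-7, ~1.8-SD separation is checked against the closed-form
noncentral-t power.

## Problem sizes and tolerances

Tests run on the protocol-typical sizes (60 s × 10 kHz spectra, 40-pulse
trains, 120 s PSC traces, 200-seed coverage loops, 2000-replicate null
simulations) and complete in well under a minute. Numerical tolerances:
1 % for power conservation, one FFT bin for frequency recovery, one
sample for correlogram lags, 5 % for rate/pool recoveries, 0.1 V for
half-max recovery — each matched to the discretisation or stochastic
floor of the quantity, not to the implementation.
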