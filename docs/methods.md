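# Methods

This note records the models behind each pipeline, the defaults that
matter, the numerical choices, and what the synthetic generators do and do
not emulate.

## Signals and conventions

Potentials are in mV, time in s, frequency in Hz, spectral density in
mV²/Hz, fluorescence in arbitrary units. Traces are uniformly sampled
(LFP default 10 kHz); segments `[t0, t0+T)` are half-open so adjacent 30-s
segments never share a sample. CSV/JSON exchange uses one dialect
(comma, `.` decimal, UTF-8, header required); no proprietary acquisition
formats are read.

## Gamma pipeline

**Spectral estimation.** Welch PSD with a Hamming window of 8192 samples,
50% overlap, per-window linear detrend, one-sided density scaling. The bin
width is exactly `sampling_rate / window_length` (1.220703125 Hz at
10 kHz); the density integrates to the signal variance (verified to 5% on
white noise). The conditioning filter is a 4th-order Butterworth low-pass
at 200 Hz applied forward–backward; only the corner frequency is a
protocol constant, the order and zero-phase application are this package's
choices (zero-phase preserves event timing; the effective response is the
squared one-pass response).

**Peak metrics.** Peak = argmax of density over the search band
(default 20–80 Hz, configurable; ties break toward the lower frequency,
deterministically). FWHM measures the half-maximum width from a *local*
baseline — the minimum density inside the search band — so a 1/f floor
does not inflate the width; crossings are linearly interpolated between
bins, and a flank that never descends below half-maximum yields an
"undefined" flag rather than an exception. Whether peak power should be
background-subtracted before the FWHM is not a settled convention; the
local-baseline rule is declared in the output.

**Presence criterion.** Each of ten 30-s segments is band-passed to
20–80 Hz (raised-cosine FFT mask), its biased normalized autocorrelation
computed to 0.5 s lag, and `A·exp(−τ/τ_d)·cos(2πfτ)` fitted by
Levenberg–Marquardt with bounds (A ∈ [0,2], τ_d ∈ [0.1 ms, 5 s],
f ∈ [1, Nyquist]); the frequency is initialized from the dominant rhythm of
the autocorrelation itself. A segment is *accepted* when the fit converged,
R² ≥ 0.5, τ_d ∈ [2 ms, 5 s], τ_d·f ≥ 1.5 cycles, and f ≥ the frequency
threshold (default 20 Hz). The persistence term (τ_d·f) is essential:
band-limiting *any* noise to 20–80 Hz produces an oscillatory
autocorrelation that a damped cosine fits with R² ≈ 0.8 but which
decorrelates within ~0.4 cycles (bandwidth-limited correlation), whereas a
genuine gamma rhythm persists for several cycles. With this criterion the
classifier scores ≥ 9/10 sensitivity on default simulated gamma and 0/20
false positives on pink-noise controls. A recording is "present" when
≥ 6/10 segments are accepted *and* the full-record spectral peak is at or
above the threshold. All thresholds are logged into every `GammaMetrics`.
The ≥ 20 Hz threshold is exposed as a plain configurable number; no
temperature-correction (Q10) model is implemented.

**Morlet spectrogram.** Complex Morlet (`cmor1.5-1.0`) magnitude via
PyWavelets, after decimating to 500 Hz by default. Visualization grade
only; the classifier never consumes it.

## Sharp wave–ripple pipeline

FFT filters mask the spectrum with raised-cosine transitions (half-width
5 Hz, configurable): a hard mask rings, and the ramp confines edge
artefacts to roughly twice the transition width. The slow (< 45 Hz) and
ripple (120–400 Hz) components both come from the same raw trace.

Detection operates on the slow component: candidates are local maxima of
|x − median| above `threshold_sd` (default 4) robust SD (1.4826 × MAD);
peaks closer than 30 ms merge keeping the larger; events within 50 ms of a
trace edge are discarded. Amplitude is the absolute deflection from the
median — the published event-detection threshold and amplitude reference
are not stated anywhere authoritative, so these are declared defaults
(chosen for > 95% recovery on the default simulator) and are logged into
every summary. Detection is exactly translation-invariant and
scale-equivariant because the threshold is relative.

Ripple frequency per event: Hann-windowed periodogram of the ripple band
inside the ±50 ms event window, peak bin refined by parabolic
interpolation (sub-bin precision ~1 Hz at a 10 Hz bin). The estimate is
suppressed (None) when the window's ripple-band mean-square power is below
2× the event-free baseline power — an event without a genuine ripple
reports no frequency rather than a noise peak.

## Laconic FRET pipeline

The sensor model is single-site saturable binding (Hill coefficient 1):
R = r_min + (r_max − r_min)·L/(L + kd). Intracellular lactate L relaxes
first-order toward each protocol segment's drive level (`rise_tau` 20 s up;
`decay_tau` 15 s down — depletion by pyruvate transacceleration is fast).
Defaults r_min = 1.0, r_max = 1.2 give the sensor's ~20 Δ% dynamic range;
kd = 0.2 mM and a resting lactate of 0.08 mM put the baseline at ~29%
occupancy, a substantial basal signal. These absolute values are free
parameters of the simulator (raw-trace amplitudes are not published
quantities); only their ratios matter to the pipeline.

Calibration takes robust plateaus (median of the final third of each
window) for r_max (saturating lactate) and r_min (pyruvate); medians
tolerate the drift visible in real sensor traces. Δ% is
100·(R − r_min)/r_min — "normalized to the minimum" admits either a
subtractive or divisive reading; the divisive convention is declared in
every output. Transport-stop metrics: baseline = median of 60 s pre-onset;
plateau = median of the final 20% of the post-onset window; time-to-90% is
the first crossing of baseline + 0.9·plateau on a 5-frame running median
(raw first-crossing is biased early by frame noise); a tail slope above
0.01 Δ%/s flags the trace as non-saturated. For a first-order rise the
closed form is t90 = τ·ln 10 ≈ 2.303 τ (52 s → ~120 s); the saturable
readout compresses this slightly (~5% for small steps), which the tests
account for. Stimulation metrics read a 3-frame median-smoothed Δ% at
fixed delays after onset, baseline-subtracted. QC excludes any trace whose
baseline ratio exceeds r_min + 0.9·(r_max − r_min) (strict inequality):
a near-saturated sensor carries no usable signal.

Not modelled: motion, bleaching beyond background subtraction, calcium/pH
crosstalk, absolute lactate concentrations (outputs are Δ%, not mM), and
biophysical network simulation on the LFP side.

## Statistics

**Fisher exact (authored here).** With margins fixed, cell (1,1) is
hypergeometric. All admissible tables are enumerated with exact integer
binomial coefficients; the two-sided p is the rational sum of
probabilities of tables whose integer weight is ≤ the observed weight —
no floating-point comparison is involved, so the "≤" is exact. A zero
margin returns p = 1 with a degenerate flag. This classical two-sided rule
reproduces the published presence-fraction p-values (0.0004, 0.016, 0.006)
and matches a float hypergeometric-summation oracle on every table with
N ≤ 40.

**Friedman + Conover.** Within-subject ranks with mean ranks on ties;
tie-corrected chi-square T1 = (k−1)·Σ(R_j − n(k+1)/2)²/(A − C) on k−1 df
(A = Σ rank², C = nk(k+1)²/4). Conover pairwise statistic
t = (R_i − R_j)/√(2n(A−C)(1 − T1/(n(k−1)))/((n−1)(k−1))) on (n−1)(k−1) df,
two-sided, unadjusted by default (an optional Holm flag exists). All-tied
input returns statistic 0 and unit p-values; a saturated T1 (perfect
separation) returns zero p off-diagonal rather than dividing by zero. The
t reference was validated against the within-block permutation
distribution of the same statistic (agreement within Monte-Carlo error).

**Standard tests** (unpaired/paired t, Mann–Whitney, Wilcoxon,
Shapiro–Wilk) dispatch to scipy.stats; identical paired samples
short-circuit to (statistic 0, p 1) where the t statistic is 0/0.

## Synthetic generators

All generators are pure functions of (parameters, seed) via
`numpy.random.default_rng`.

- **Gamma**: phase-diffusion oscillator — amplitude·cos(φ) with
  dφ = 2πf₀dt + N(0, D·dt), on 1/f background (spectral shaping of white
  noise, slope −1, rescaled to an exact SD). The Wiener phase gives a
  Lorentzian line with FWHM = D/(2π) Hz and an autocorrelation envelope
  decaying with τ = 2/D — amplitude and jitter are therefore independent
  knobs for peak power and FWHM. Defaults: 40 Hz, 0.1 mV amplitude,
  D = 20 rad²/s (FWHM ≈ 3.2 Hz), 0.05 mV background.
- **SPW-R**: Poisson event train with a 50 ms non-paralyzable refractory
  period; candidates are drawn at the dead-time-corrected rate
  λ/(1 − λ·refractory) so the realized rate equals the nominal incidence
  (3/s default, ~900 events per 300 s). Each event is a Gaussian-envelope
  sharp wave (0.3 mV peak, 50 ms envelope FWHM) plus the same envelope
  windowing a 250 Hz sinusoid (0.06 mV).
- **Laconic**: see above; channel intensities are synthesized with a
  constant FRET channel so that background-subtracted mTFP/FRET reproduces
  the noisy model ratio exactly.

What the generators do **not** emulate: non-stationary drift of gamma
frequency over recording time, waveform asymmetry/biphasic sharp waves,
inter-slice variability of amplitudes, imaging bleaching and movement.
Passing recovery tests therefore demonstrates correctness of the
estimators under the stated signal models, not robustness to every
artefact of real recordings.

## Problem sizes and tolerances in the test suite

Recovery sweeps run at 2–2.5 kHz sampling where the quantity under test is
fully resolved below 400 Hz, keeping simulation sizes modest; canonical
bin-geometry and filter checks run at 10 kHz. Stochastic checks fix their
seeds and use Poisson (3σ) or Monte-Carlo error bounds stated inline. The
acceptance script simulates at full 10 kHz/300 s.

## Known limitations

- The presence criterion's acceptance thresholds (R² ≥ 0.5, 1.5 cycles)
  are operational choices; alternative operationalizations (e.g. fitting
  only the autocorrelation envelope) are defensible and would shift
  borderline calls.
- FFT-mask filtering is circular; analyses near trace edges inherit ~2×
  the transition width of edge effect, and SPW-R events within 50 ms of an
  edge are dropped for this reason.
- The Fisher test enumerates in exact arithmetic and is O(min(r1,c1));
  fine for slice counts, not meant for large epidemiological tables.
- Friedman/Conover requires complete blocks; no imputation is offered.
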