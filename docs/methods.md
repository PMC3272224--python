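# Methods

This note documents the models, conventions and numerical choices behind
`barovar`, in the order data flows through the package.

## Beat extraction

Systolic peaks are located with a prominence/refractory peak detector
(`scipy.signal.find_peaks`): default refractory 100 ms (caps detectable HR at
600 beats·min⁻¹, above any physiological rat value) and prominence 10 mmHg
(about a third of a typical rat pulse pressure). PI is measured
systole-to-systole because the systolic upstroke is the sharpest landmark of
the pulse wave; DBP is the minimum of the inter-systolic interval *preceding*
each peak (the other convention — the following minimum — differs only by a
one-beat shift of the DBP series and is not exposed). The first beat has no
preceding interval, so its PI and HR are stored as missing rather than
extrapolated. No artifact rejection is applied by default; an optional filter
rejecting beats with PI outside median ± 50 % is available for ectopic or
movement-artifact segments.

## Sequence-method baroreflex

Ramps are *maximal* runs of strictly monotonic SBP (per-step change strictly
greater than `delta_sbp`, default 0) of at least `min_len = 4` beats; a
6-beat run is one ramp, not three overlapping 4-beat ramps, which keeps the
BEI denominator interpretable. The same 4-beat threshold applies to both
directions. For each ramp the PI stream delayed by each candidate lag
(default {3, 4, 5} beats) is tested for same-direction strict monotonicity
over the ramp's length; among qualifying lags the largest |r| wins, so a ramp
contributes at most one sequence and BEI ≤ 1. Sequences must reach
`r_min = 0.85` (standard sequence-method practice; the threshold is logged
and configurable) and a positive slope — an SBP rise answered by PI
shortening is reflex-inconsistent and ignored. A ramp so close to the series
end that its PI window would overrun at some candidate lag is skipped
entirely and excluded from the BEI denominator: it cannot be fully evaluated,
and counting it would deflate BEI on fully coupled data.

Slopes are ordinary least squares of PI on SBP (`scipy.stats.linregress`);
BRS is the unweighted mean of per-sequence slopes (no length weighting). The
operating range pools every beat-level (SBP, PI) pair of every sequence and
takes the central 95 % per axis as the 2.5th–97.5th percentile width
(linear-interpolation percentile definition), the rectangle area being the
product of the two widths; the set point is the component-wise median of the
same pooled points. With zero sequences, counts are reported and all other
fields are missing.

## Variability spectra

The beat-indexed series is linearly interpolated onto a uniform 20 Hz grid
spanning the valid beats (the HR grid starts at the second beat, whose HR is
the first defined value); no extrapolation. The nine-point Hanning filter is
a zero-phase FIR smoother with coefficients w_k ∝ sin²(πk/8), k = 0…8
(endpoints zero), normalized to unit sum, applied with reflect padding — a
smoothing filter on the signal, not a per-segment taper (a per-segment Hann
taper is available as an option, off by default). Band powers are *not*
compensated for the filter's passband attenuation; the filter can be
disabled, and the spectral acceptance checks run with it off.

Each analysis window (default 410 s, i.e. 8200 samples) is cut into
`n_segments = 15` segments of `nfft = 2048` samples advancing by
⌊(N − nfft)/(n_seg − 1)⌋ samples — the overlap follows from (N, nfft,
n_segments) rather than being fixed at 50 %, because 15 segments of 2048
points in 8200 samples force ≈ 79 % overlap. Each segment is independently
linearly detrended. Per segment the one-sided FFT bin powers are scaled so
that their sum (DC excluded) equals the segment variance (Parseval); bin
width is rate/nfft ≈ 0.00977 Hz. Band membership is by bin centre frequency
in the half-open interval [low, high), so VLF ∪ LF ∪ HF partitions the total
interval [0.0195, 3) Hz exactly and band powers are additive by construction;
a bin at exactly 0.8 Hz belongs to HF. Normalized units divide each band by
the total over [0.0195, 3) Hz (VLF included). The HF peak frequency is the
centre of the maximal averaged bin inside HF. Spectra of a constant signal
are all-zero with the ratio and peak undefined.

## Synthetic generator

The generator is a beat-by-beat recursion. SBP is a mean plus sinusoidal
components evaluated in continuous time *at the irregular beat times*, so the
spectral path sees the same uneven-sampling distortions as real data. The
pulse interval preceding beat n is

    PI_n = 60000 / mean_hr + G · (SBP_{n−lag} − mean_sbp) + η_n

when the reflex is engaged for source beat n − lag, otherwise the baseline
plus noise; beat times advance by PI_n/1000. Storing PI_n as the interval
*ending* at beat n keeps one PI convention across the generator, the beat
detector and the file format, and makes the sequence-method lag equal the
generator's lag exactly. HR-band oscillations enter through PI, converted
from beats·min⁻¹ at the operating point (|dPI| = 60000/HR̄² · dHR), keeping
PI the primitive variable. DBP is SBP minus a constant pulse pressure.

Reflex engagement is drawn once per monotonic SBP run (Bernoulli with
`coupling_prob`) and applied per beat; a turning-point beat shared by two
runs is engaged if *either* run is. This makes an engaged ramp coupled over
its whole response window, so the effectiveness index is binomial around the
coupling probability — the property the BEI calibration checks assert. An
independent per-beat draw would instead give BEI ≈ p^L for ramp length L,
which no sequence analysis could read as p.

Presets: `wistar_baseline` and `bhr_baseline` use published baseline group
means of normotensive Wistar and borderline hypertensive rats (SBP 109/134,
DBP 79/99 mmHg, HR 352/328 beats·min⁻¹, reflex gain 1.5/2.2 ms·mmHg⁻¹) as
generative parameters, with a slow vasomotor component (0.08 Hz), a Mayer
wave (0.4 Hz), a respiratory component (1.33 Hz), 3 mmHg SBP noise and 2 ms
PI noise — magnitudes chosen to put band powers in the few-mmHg² range
typical of rat telemetry. The demo presets isolate one component each.
`render_waveform` draws, per inter-systolic interval, an exponential-like
decay from the previous SBP to the next DBP followed by a raised-cosine
upstroke spanning 30 % of the interval, so systolic peaks fall exactly on
beat times; a half-cycle lead-in and tail make the first and last peaks
detectable. At 1000 Hz the render→detect round trip reproduces beat count
exactly, SBP/DBP to ≈ 0.03 mmHg and PI to ≈ 1 ms (grid quantization).

## What the generator does and does not emulate

It reproduces the statistical structure the analyses assume: stationary
means, narrow-band oscillations in the three bands, a lagged linear
SBP→PI reflex with partial engagement, and white measurement noise. It does
not model nonstationarity (stress transients, circadian drift), nonlinear or
saturating reflex behaviour, ectopy, respiratory sinus arrhythmia as a
mechanical (non-neural) pathway, or biophysical pressure-wave shape beyond a
plausible template. Passing tests therefore certify the *analysis chain* —
that it reads back what the generative model put in — not that real
recordings satisfy the model.

One consequence worth knowing: with the presets' physiologic noise levels,
strict-monotonicity matching accepts only ~40 % of ramps even at an
engagement probability of 0.9, because a single noisy PI step breaks a run.
Real-data BEI values depend on noise as much as on reflex engagement; the
BEI ≈ coupling-probability calibration holds in the low-noise regime.

## Pipeline, windows and determinism

Recordings are cut into non-overlapping windows (default 410 s) left-aligned
at the first beat; the window count is ⌊span/410 s⌋ and shorter inputs are an
error. How a longer registration is reduced to analysis periods is a study
design choice, so the window length and alignment are configuration, not
fixed. Summaries across windows are mean ± SEM with the n−1 standard
deviation (SEM undefined for one window). The JSON report is
schema-versioned, strict JSON (missing values are null, keys sorted), and a
pure function of input and configuration — identical inputs give
byte-identical reports. Simulations are fully reproducible from the seed.

## Problem sizes used in checks

Validation runs use 410 s windows (one registration period, ≈ 2400 beats at
rat heart rates) for gain recovery, BEI calibration and preset fidelity;
60 s renders for waveform round trips; 20 repeated simulations for noisy
recovery and per-probability BEI means. These sizes make every Monte Carlo
interval in the tests comfortably wider than the corresponding standard
error.
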