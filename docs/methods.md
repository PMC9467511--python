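# Methods

## Spectral model

Every time bin's power spectrum is decomposed, in log10-power versus
linear-frequency coordinates, into an aperiodic component plus Gaussian
peaks. The aperiodic component is

- fixed mode: `L(f) = offset − exponent · log10 f`
- knee mode: `L(f) = offset − log10(knee + f^exponent)`

with the offset in log10-power arbitrary units, the exponent in Hz⁻¹ (the
negative log-log slope), and the knee a non-negative bend parameter whose
associated knee frequency is `knee^(1/exponent)`. Each peak is
`a · exp(−(f − cf)²/(2 sd²))` with amplitude `a` measured above the
aperiodic curve. The model is additive in log power, so the corresponding
linear-power model is multiplicative.

## Per-spectrum fitting

Fitting is sequential, in the specparam style:

1. **Robust aperiodic fit.** A bounded least-squares fit of the aperiodic
   form to all points (exponent cold-start: the endpoint log-log slope
   `|log P(f_min) − log P(f_max)| / (log f_max − log f_min)`; knee
   cold-start 0; warm starts replace the exponent initialization only).
   The spectrum is then flattened, negative residuals clipped to zero,
   and the fit repeated on the points at or below the 2.5th percentile of
   the positive residuals. This deliberately fits the *lower envelope*,
   so peak regions cannot drag the aperiodic estimate upward.
2. **Peak extraction.** Iteratively take the tallest point of the
   flattened spectrum while it exceeds both `peak_threshold` (2 by
   default) standard deviations of the current flattened spectrum and the
   absolute `min_peak_height` (0.6 a.u.); guess the SD from the
   half-height width (clipped to half the peak-width limits), subtract
   the guess Gaussian, and repeat up to `max_n_peaks`. Equal maxima
   resolve to the lower frequency.
3. **Joint Gaussian refit** of all guesses by bounded least squares, with
   each centre frequency confined to its guess ± 2 guess-SDs (clipped to
   the fitted range) so peaks cannot migrate.
4. **Proximity pruning.** Peaks closer than `proximity_threshold` × their
   SD to a band edge are dropped; of any pair closer than the threshold
   times the larger SD in centre frequency, the lower-amplitude peak is
   dropped; repeated until stable. Pruning only removes peaks, never
   alters survivors.
5. **Self-consistency refinement.** The stage-1 aperiodic estimate is
   made with the peaks still present, which biases the flattened spectrum
   the peaks were fit to. The fit therefore alternates a plain (all
   points) aperiodic fit of the peak-subtracted spectrum with a peak
   refit against the new flattened spectrum, stopping when parameters
   move < 1e-4 or when the alternation stops contracting by at least 30%
   per pass (beyond that point it only chases residual noise). On
   noiseless model spectra this converges to the exact parameters; the
   round-trip recovery is asserted at 1e-3 in the tests.
6. **Final aperiodic fit** of the peak-subtracted spectrum using *all*
   points. This matters: refitting the lower envelope here would bias the
   offset low by roughly 0.8× the per-bin noise SD under noisy
   spectra, while the robust envelope stage is still essential earlier
   to expose the peaks.
7. **Goodness of fit**: MAE and the squared Pearson correlation between
   the modelled and observed log spectrum (R² undefined for
   zero-variance input).

In knee mode, fits whose exponent leaves (−5, 5) Hz⁻¹ are flagged
(`exponent_out_of_range`) and excluded from downstream aggregation rather
than interpolated; in the knee benchmark this affects ≈2% of bins.

## Time-resolved tracking

The spectrogram front-end computes Hann-windowed one-sided PSDs (Welch
density normalization: a cosine of amplitude A integrates to A²/2) on
1 s windows with 50% overlap, and averages the power of 5 consecutive
windows — centred on each emitted bin — so bins are spaced 0.5 s and the
time axis loses two window-steps at each end. Bins are fitted in temporal
order, each warm-starting only the aperiodic exponent from its
predecessor. Per-bin optimizer warnings are collected in the fit status,
never aborting a run.

Outlier-peak pruning then removes peaks with fewer than `n_required`
(default 3) other peaks of similar frequency (within 2.5 Hz) among the
bins up to 6 bins away on either side (±3 s at the default step),
counting on the *original* peak set and applying all removals in a single
pass, so removals cannot cascade. Where peaks were removed, the aperiodic
component is refit against the spectrum minus the surviving peak model
and the goodness of fit recomputed; untouched bins are never altered.

A Morlet-wavelet comparator mirrors the published alternative: complex
Morlet transform (central frequency 3 Hz, envelope FWHM 1 s, scaling ∝
1/f), per-frequency Gaussian temporal smoothing (SD 1 s) truncated at
±3.5 s — which reproduces the published 3.5–56.5 s valid range on a 60 s
recording — and independent per-bin parameterization on a time axis
decimated to the 0.5 s bin step of the STFT path (parameterizing every
5 ms sample adds nothing at these smoothing scales).

## Simulator

A trial is defined by a target log10-power spectrogram: a
piecewise-linear-in-time aperiodic trajectory (optionally with a constant
knee) plus peak events whose amplitude is tapered by a Tukey window
(cosine fraction 0.4) and whose centre frequency may chirp linearly. The
signal is a bank of cosines on the trial's Fourier grid (spacing
1/duration ≈ 0.017 Hz; time resolution one sample, 0.005 s at the default
200 Hz):

```
x(t) = Σ_f a_f(t) cos(2π f t + φ_f),
a_f(t) = sqrt(2 · 10^S(f,t) · Δf) · |W(f)| / sqrt(E|W|²)
```

with independent uniform phases and per-frequency magnitudes from the
Fourier modulus of a unit-variance white-noise seed series. The
normalization by `sqrt(E|W|²)` makes the *expected* PSD equal the target
exactly; the Rayleigh-distributed modulus contributes naturalistic
per-frequency power jitter (≈0.056 log10 units per 1 Hz analysis bin,
constant within a trial). Trial-averaged Welch log-PSDs match the target
within 0.1 a.u. per in-band bin (asserted over 50 trials).

Two numerical choices matter:

- **Low-frequency plateau.** The fixed aperiodic form diverges as f → 0;
  synthesizing that divergence leaks spurious power into the lowest
  analyzed bins through the 1 s Hann window's kernel (+0.5 log10 units at
  the 1 Hz bin for typical exponents). Real neural spectra flatten at
  very low frequencies, so the synthesized aperiodic curve is held
  constant below 0.8 Hz — the floor at which the Hann power kernel is
  unbiased (< 0.01 log10 units) at a 1 Hz bin for exponents 1.5–2, as
  computed from the kernel itself. The target spectrogram at and above
  1 Hz is unaffected.
- **Fast exact evaluation.** The naive double sum is O(F·T). It is
  evaluated exactly instead via inverse FFTs on stationary trajectory
  segments, an exact power-series factorization of the ramp factor
  `exp(s(t)·w(f))` in fixed mode, and dense evaluation only on knee-mode
  ramp columns and on peak patches (Gaussians truncated at 5 SD, where
  the amplitude correction is < 4e-6; peaks overlapping in both time and
  frequency are evaluated jointly so the additive log-power model stays
  exact). The result agrees with the naive cosine bank to ~1e-12 relative
  (tested), and regeneration from the same seed is bit-identical.

The three benchmark designs follow the published simulation studies: the
fixed transient/chirp design; the randomized design (exponent 0.8–2.2,
offset −8.1…−1.5, a single linear shift of both within the trial, 0–4
peaks with cf 3–35 Hz, amplitude 0.6–1.6, SD 1–2 Hz, and ≥2.5 max-SD
centre-frequency separation for temporally overlapping peaks, enforced by
bounded rejection-resampling); and the knee design (knee frequency
uniform on 0–30 Hz, stored as `k = f_k^χ` using the trial's initial
exponent since the knee parameter is constant while the exponent drifts;
two peaks in 3–30 and 30–80 Hz analyzed over 1–100 Hz).

## Evaluation

A fitted peak is matched to a ground-truth event active at its bin when
its centre frequency lies within 2.5 *truth* SDs of the event's (possibly
chirping) centre frequency at that time; the highest-amplitude candidate
is labelled correct and consumes the event, the rest are incorrect, and
active events without candidates are missed. Sensitivity in the
randomized and knee benchmarks is correct detections over expected
peak-bins (bins whose centre lies in an event's half-open [onset, offset)
interval); specificity is correct peaks over all fitted peaks. In the
transient/chirp benchmark, band-wise sensitivity is evaluated on Tukey
*plateau* bins (envelope = 1) as the fraction with an in-band detection,
and specificity as the fraction of event-free bins without an in-band
detection. Parameter MAEs pool all contributing bins (aperiodic) or
correct matches (peak parameters, with amplitude compared against the
tapered truth amplitude at the bin time) with equal weights.

## Parameters that matter

| parameter | default | units | role |
| --- | --- | --- | --- |
| window_length | 1 | s | spectral (1 Hz) vs temporal resolution |
| overlap_fraction | 0.5 | – | bin spacing = window·(1−overlap) |
| n_average | 5 | windows | per-bin noise (≈0.22 log10 SD at default) |
| freq_range | 1–40 | Hz | fitted band (1–100 Hz in knee benchmark) |
| peak_width_limits | 0.5–6 | Hz | Gaussian SD bounds = half these |
| max_n_peaks | 3 | – | 6 in the randomized benchmark |
| min_peak_height | 0.6 | a.u. | absolute detection floor |
| peak_threshold | 2 | SD | relative detection floor |
| proximity_threshold | 2 | SD | edge/overlap pruning |
| outlier n/freq/time | 3 / 2.5 Hz / 6 bins | – | transient-peak removal |

## What the simulations do and do not show

The simulator reproduces the statistical structure the method is designed
for — drifting 1/f backgrounds, tapered and chirping narrow-band bursts,
realistic spectral estimation noise — but not volume conduction,
artifacts, non-sinusoidal waveform shape, line noise, or
multichannel structure. Passing benchmarks therefore demonstrate
correctness of the estimation machinery under the stated generative
model, not robustness to everything real recordings contain.

Known limitations, visible in the benchmarks: peak bandwidth is
overestimated at 1 Hz spectral resolution; low-frequency peaks (< 8 Hz)
are harder to separate from the aperiodic edge; at most ~2 simultaneous
peaks are reliably resolved; knee-mode fitting is markedly harder (the
knee parameter is ill-conditioned, and its frequency-domain errors have
heavy tails). The per-bin noise of the default 5-window estimate (log10
SD ≈ 0.22) sets a floor on model-versus-truth spectrogram error of
roughly 0.08 a.u.; halving it requires ~4× the averaging and
correspondingly coarser temporal resolution.
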