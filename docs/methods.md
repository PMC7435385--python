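# Methods

## Signal model and processing chain

The package treats a PPG recording as a uniformly sampled series
x(n) = x(t₀ + n/fs) (default fs = 128 Hz) composed of a static DC perfusion
level, a quasi-periodic pulsatile cardiogenic component in the
physiological band, slow baseline wander, transient motion artifacts, and
broadband sensor noise. Heart rate is estimated by isolating the pulsatile
component and counting its peaks:

1. **Normalisation** to zero mean and unit variance. Population (1/N)
   moments are used throughout (configurable to the sample convention);
   skewness and the SQIs use the same convention so indices are comparable
   across segments of different lengths.
2. **Zero-phase Butterworth band-limiting**, 2nd-order high-pass at 0.5 Hz
   and 1st-order low-pass at 6 Hz, applied forward–backward so pulse-wave
   timing is preserved (no phase distortion). Forward–backward application
   squares each magnitude response and would pull the realised −3 dB points
   inside the design cutoffs, so by default the single-pass prototype
   corners are pre-shifted by (√2 − 1)^(1/2n) (the standard zero-lag
   Butterworth correction); the realised zero-phase filters are then −3 dB
   exactly at 0.5 and 6 Hz, and a 3 Hz passband tone keeps ≈ 0.91 of its
   amplitude. Edge transients are handled by reflect padding of
   3·fs/hp_fc samples (≈ 3 high-pass settling lengths) before filtering.
3. **Optional acceleration plethysmogram** (APG): second time-derivative by
   central differences scaled by fs² (one-sided at the endpoints; exact for
   quadratics). Differentiation re-weights the spectrum by ω², so when the
   APG feeds the CWT the scale set should be centred on the pulse
   fundamental — with the default broad cardiac band the second harmonic
   dominates and the count doubles. The default pipeline therefore feeds
   the **filtered PPG** to the CWT; `use_apg` switches routes.
4. **CWT via FFT** with DOG wavelets (below), five log-spaced scales whose
   centre frequencies span 0.8–3.3 Hz (≈ 48–200 bpm, covering resting and
   stressed pig heart rates).
5. **Cardiac reconstruction**: real part of the column-wise sum of
   coefficient rows (a band-limited approximation of the inverse CWT over
   the retained scales; robust when the pulse frequency drifts between
   scales). A `max_energy` mode keeps only the highest-energy scale.
   Because a discrete ad-hoc scale set reconstructs band content only up
   to a constant admissibility gain, the pipeline rescales the
   reconstruction by the least-squares projection coefficient
   ⟨filtered, recon⟩/⟨recon, recon⟩ before any amplitude-sensitive use
   (noise residual, SNR index). Peak detection and bpm are scale-free and
   unaffected by this gain.
6. **Peak detection**: greedy tallest-peak iteration — take the global
   maximum, suppress ± 0.27 s around it (refractory period, bounding the
   detectable rate at ≈ 220 bpm), repeat; stop when the next candidate
   falls below 0.30 × the median accepted amplitude or is non-positive.
   The stopping fraction is scale-free, hence robust to amplitude drift;
   ties break toward the earlier sample for determinism.
7. **Heart rate**: count of detected peaks per half-open sliding window of
   60 s advanced by 30 s (50 % overlap), × 60/window. With the one-minute
   window the count is the bpm; an interval-based estimate
   (60 / mean inter-peak interval) is available but not default because
   counting is what the window/overlap design implies. Epochs exist only
   where a full window fits.

## DOG wavelets and the FFT route

Fourier-domain definition, order m ≥ 1:

ψ̂(sω) = (1/√Γ(m+½)) (i·sω)^m e^(−(sω)²/2)

Even orders are real and symmetric in the Fourier domain (m = 2 is the
Mexican hat); on a real signal they give real coefficients and one positive
maximum per pulse, which is why only the maxima are used for beat counting
and the default order is m = 4 (orders 2/4/6 selectable; odd orders require
an explicit opt-in). |ψ̂| peaks at |sω| = √m, giving the scale↔frequency
map f_c(s) = √m/(2πs) with s in seconds.

Per scale, coefficients are the inverse DFT of x̂(ω_k)·ψ̂*(sω_k) with the
√(2πs/Δt) renormalisation, which keeps Σ_k |ψ̂(sω_k)|² constant (= N)
across scales so coefficient magnitudes are energy-comparable. The DFT
length equals the signal length (no zero padding), preserving sample
alignment; edge effects are circular and negligible because analysis
segments (60 s) are long relative to the wavelet support. Bins above N/2
map to negative angular frequencies before evaluating ψ̂, preserving
conjugate symmetry.

The time-domain closed form ψ_m(t) = (−1)^m He_m(t) e^(−t²/2) / √(2π Γ(m+½))
(He_m the probabilists' Hermite polynomial) backs an O(N²) direct-quadrature
implementation used as an independent test oracle; the two routes agree to
< 0.01 % of the peak coefficient on central samples when scales are a few
samples wide and supports stay inside the record (at very small scales the
sampled time-domain wavelet aliases, at very large ones circular wrap-around
reaches the centre — both are resolution limits of the comparison, not of
the transform).

## Signal-quality indices

Per 60-s segment (segment length is configurable; 60 s at 128 Hz is
7680 samples):

- **PSQI** = (X_max − X_min)/|x̄| × 100, pulsatile range of the *filtered*
  segment over the mean of the *raw* (pre-normalisation) segment. The raw
  mean is the static blood-flow level; after normalisation the mean is zero
  and the index would be undefined, so the pipeline always computes it from
  the raw signal and rejects near-zero-mean input with a pointed error.
- **SSQI** = population skewness of the filtered segment; near 0 for clean
  symmetric pulse trains, drifting away under corruption.
- **SNSQI** = σ²(|cardiac|)/σ²(noise), with the noise taken as the residual
  filtered − cardiac after the calibrated reconstruction — the only noise
  reference the pipeline itself can construct. The absolute value in the
  numerator follows the index's definition as a ratio of the rectified
  pulsatile level to background noise.

## Synthetic generator

`SyntheticConfig`/`generate` emulate the statistical structure the
algorithm assumes, with exact ground-truth beat times:

- **Beats**: the piecewise-linear bpm profile is integrated to a phase;
  beats fall at half-integer phase crossings, then inter-beat intervals are
  jittered multiplicatively (sd `hr_jitter_pct`, default 2 %, truncated at
  ± 3 sd). A constant profile with zero jitter gives exactly
  duration·bpm/60 uniformly spaced beats.
- **Pulse shape**: unit-amplitude systolic Gaussian (sd 0.06 s) plus a
  dicrotic Gaussian of 0.35× amplitude, 0.22 s later and 1.5× wider — the
  two-lobed morphology of a peripheral pulse without a full Windkessel
  model. 0.06 s keeps the pulse distinct at 200 bpm while placing most
  energy at the fundamental.
- **Wander**: three random-phase sinusoids in 0.05–0.4 Hz with total
  amplitude 1.5 pulse units — strictly below the 0.5 Hz high-pass corner,
  the premise the preprocessing exploits.
- **Artifacts**: `rate × duration/60` Hann bursts of 2 s and 5× pulse
  amplitude at uniform random onsets (rate default 0; 2–4/min emulates a
  moving animal). A per-sample boolean mask is reproducible from the
  config alone for stratified evaluation.
- **Noise**: additive white Gaussian, sd 0.1 pulse units.
- **Baseline**: DC level 10 so the perfusion index is defined on raw input.

All draws descend from one mandatory root seed through four independent
substreams (beats/wander/artifacts/noise), so the mask regenerates without
the signal and identical seeds are bit-identical.

What the generator does *not* emulate: pulse-morphology variation with
vascular tone, amplitude modulation by respiration, sensor saturation and
contact-pressure drift, broadband (non-smooth) motion artifacts, and
heart-rate variability structure beyond white inter-beat jitter. Passing
tests therefore demonstrate that the chain recovers rates whose components
occupy the assumed bands — not performance on any particular animal
recording.

## Validation problem sizes and numerical choices

The test suite and `scripts/acceptance.py` use 5-min recordings at 128 Hz
(nine 60-s epochs) for recovery checks, 256-sample records for the O(N²)
oracle comparison, and 10⁶ draws for distributional SQI checks; these
sizes give stable statistics at desk scale. Other choices:

- Zero-variance inputs (normalisation, skewness, SNR denominators) raise
  errors rather than returning NaN; an all-zero scalogram yields uniform
  energy fractions with a warning; a constant peak-detection input yields
  an empty peak list with a warning.
- Segment boundaries, epoch windows and peak-time windows are all
  half-open [start, end); indices 0-based; sample n at t₀ + n/fs.
- Trailing partial segments/epochs are dropped (and logged), never padded.
- The Wilcoxon signed-rank test (two-sided, paired per segment) backs
  wavelet-order comparisons because per-segment errors are small-sample
  and non-normal; identical error vectors report p = 1; fewer than six
  segments yields summary statistics without p-values and a warning. A
  paired t-test is a one-line swap.

## Known limitations

- With frequent artifacts (≥ 4 bursts/min) every 60-s epoch overlaps some
  burst, so the clean/contaminated stratification degenerates; stratified
  reporting is most informative below ~1 burst/min or with shorter windows.
- The count-based bpm quantises to ± 1 beat per window; sub-bpm resolution
  requires the interval-based option.
- The literal power-of-two scale exponents [2^0.16 … 2^0.50] remain
  constructible (`ScaleSet.from_exponents`) but are far outside the
  cardiac band under the seconds-based scale convention at fs = 128 Hz;
  the band-derived default is recommended.
- APG mode requires a fundamental-centred scale set (see above).
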