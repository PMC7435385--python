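# ppghr — motion-tolerant heart-rate estimation from PPG

`ppghr` estimates heart rate (beats per minute) from a single-channel
photoplethysmography (PPG) recording, designed for noisy, motion-contaminated
signals such as wearable sensors on livestock (its scale defaults target the
pig cardiac band, ≈48–200 bpm). It is aimed at physiologists and
animal-welfare researchers who need continuous, non-invasive heart-rate
monitoring without an ECG harness, and at signal-processing practitioners who
want a tested, reproducible CWT-based pulse extractor.

## Method

The pulsatile cardiogenic component is decoupled from wander and noise with a
continuous wavelet transform computed by FFT. For scale *s* > 0 and position
*b*,

    C(s, b) = ∫ x(t) (1/√s) ψ*((t − b)/s) dt

is evaluated per scale as the inverse DFT of x̂(ω)·ψ̂\*(sω), with each scaled
wavelet renormalised by √(2πs/Δt) to unit energy. The mother wavelet is the
m-th derivative of a Gaussian (DOG),

    ψ̂(sω) = (1/√Γ(m+½)) (i·sω)^m exp(−(sω)²/2),

with even order m = 4 by default (m ∈ {2, 4, 6} supported); even orders are
symmetric, so each cardiac pulse maps onto a single positive coefficient
maximum. Five log-spaced scales cover the cardiac band 0.8–3.3 Hz
(centre frequency f_c = √m / 2πs).

The full chain: normalise to zero mean/unit variance → zero-phase Butterworth
band-limiting (2nd-order 0.5 Hz high-pass, 1st-order 6 Hz low-pass) → CWT →
cardiac reconstruction (sum of coefficient rows across scales) → iterative
tallest-peak detection with a 0.27 s refractory period → bpm per sliding
60-s epoch with 50 % overlap. Per-segment signal-quality indices are
reported alongside: perfusion PSQI = (X_max − X_min)/|x̄| × 100, skewness
SSQI = (1/N)Σ[(xₙ−μ̂)/σ]³, and SNR SNSQI = σ²(|signal|)/σ²(noise).
Agreement with a reference is summarised by MAE, RMSE and overall accuracy
100·(1 − mean relative absolute error).

A synthetic PPG generator with exact ground-truth beat times (two-Gaussian
pulses, sub-0.5 Hz wander, Hann-burst motion artifacts, white noise)
supports validation without animal recordings.

## Worked example

```
ppghr simulate --seed 42 --duration 300 --bpm 96 --artifact-rate 2 \
    --out-signal sig.csv --out-beats beats.csv
ppghr hr sig.csv --out-hr hr.csv --out-sqi sqi.csv
ppghr evaluate --est hr.csv --ref beats.csv --duration 300 --out report.json
```

The final command logs

```
INFO ppghr: evaluate: MAE 0.44 bpm, RMSE 0.82 bpm, accuracy 99.5%
```

meaning the epoch-wise PPG estimate deviates from the ground-truth beat
count by 0.44 bpm on average across the nine 60-s epochs (RMSE weighs the
occasional artifact-hit epoch more heavily), and the mean relative error is
0.5 % despite two 5× motion bursts per minute. `hr.csv` holds one
`(epoch_center_s, bpm)` row per epoch; `sqi.csv` holds per-segment
perfusion/skewness/SNR indices.

The same pipeline is available as a library:

```python
from ppghr import SyntheticConfig, generate, estimate_hr

signal, beats = generate(SyntheticConfig(seed=42, duration_s=300.0))
result = estimate_hr(signal)
print(result.hr.bpm)          # bpm per 60-s epoch, 30-s hop
print(result.sqi[0])          # SQIReport(psqi=..., ssqi=..., snsqi=...)
```

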