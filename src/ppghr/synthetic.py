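"""Synthetic PPG generator with exact ground-truth beat times.

Emulates the statistical structure the estimation pipeline assumes in a
peripheral PPG recording: quasi-periodic cardiac pulses in the
physiological band (~0.8–3.3 Hz), slow baseline wander below 0.5 Hz,
transient motion-artifact bursts, broadband sensor noise, and a static DC
perfusion level. Each beat contributes a two-Gaussian pulse (systolic peak
plus a delayed, smaller dicrotic wave). Beat times are obtained by
integrating a piecewise-linear instantaneous heart-rate profile, with
optional multiplicative inter-beat jitter.

All randomness descends from a single root seed through independent
substreams (beats, wander, artifacts, noise), so the artifact mask can be
regenerated without re-synthesising the signal and identical seeds give
bit-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid
from scipy.signal.windows import hann

from ppghr.signal_io import BeatReference, SampledSignal

__all__ = ["SyntheticConfig", "generate", "artifact_mask"]

_BEATS, _WANDER, _ARTIFACTS, _NOISE = range(4)


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of the synthetic PPG model.

    Amplitudes are relative to a unit systolic pulse peak. The defaults
    describe a moderately noisy resting recording; raise
    ``artifact_rate_per_min`` to emulate a moving animal.
    """

    seed: int  # root seed; mandatory for reproducibility
    duration_s: float = 300.0
    fs: float = 128.0
    #: piecewise-linear (time_s, bpm) breakpoints of the instantaneous HR
    hr_profile: tuple = ((0.0, 80.0), (300.0, 80.0))
    hr_jitter_pct: float = 2.0  # sd of multiplicative inter-beat jitter
    pulse_width_s: float = 0.06  # systolic Gaussian sd
    dicrotic_frac: float = 0.35  # dicrotic amplitude / systolic amplitude
    dicrotic_delay_s: float = 0.22
    wander_amp: float = 1.5  # total baseline-wander amplitude
    wander_band: tuple = (0.05, 0.4)  # Hz, below the 0.5 Hz high-pass corner
    artifact_rate_per_min: float = 0.0
    artifact_amp: float = 5.0  # Hann-burst peak, x pulse amplitude
    artifact_duration_s: float = 2.0
    noise_sd: float = 0.1  # additive white noise
    baseline: float = 10.0  # static DC level (keeps the perfusion index defined)

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not (self.duration_s > 0):
            raise ValueError("duration_s must be positive")
        if not (self.fs > 0):
            raise ValueError("fs must be positive")
        prof = np.asarray(self.hr_profile, dtype=float)
        if prof.ndim != 2 or prof.shape[1] != 2 or prof.shape[0] < 2:
            raise ValueError("hr_profile must be >= 2 (time_s, bpm) breakpoints")
        if np.any((prof[:, 1] <= 30) | (prof[:, 1] >= 250)):
            raise ValueError("hr_profile bpm must lie in (30, 250)")
        if not np.all(np.diff(prof[:, 0]) > 0):
            raise ValueError("hr_profile times must be strictly increasing")
        for name in ("hr_jitter_pct", "wander_amp", "artifact_rate_per_min",
                     "artifact_amp", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        for name in ("pulse_width_s", "dicrotic_delay_s", "artifact_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not (0 <= self.dicrotic_frac < 1):
            raise ValueError("dicrotic_frac must lie in [0, 1)")
        lo, hi = self.wander_band
        if not (0 < lo < hi):
            raise ValueError("wander_band must satisfy 0 < lo < hi")

    def replace(self, **kw) -> "SyntheticConfig":
        return replace(self, **kw)

    def _rng(self, stream: int) -> np.random.Generator:
        return np.random.default_rng([int(self.seed), stream])


def _beat_times(config: SyntheticConfig) -> np.ndarray:
    """Integrate the HR profile; beats at half-integer phase crossings."""
    prof = np.asarray(config.hr_profile, dtype=float)
    tg = np.arange(0, config.duration_s, 1.0 / config.fs)
    f_inst = np.interp(tg, prof[:, 0], prof[:, 1]) / 60.0  # Hz
    phase = cumulative_trapezoid(f_inst, tg, initial=0.0)
    targets = np.arange(0.5, phase[-1], 1.0)
    beats = np.interp(targets, phase, tg)
    if config.hr_jitter_pct > 0 and beats.size > 1:
        rng = config._rng(_BEATS)
        ibis = np.diff(beats)
        z = np.clip(rng.standard_normal(ibis.size), -3, 3)
        ibis = ibis * (1.0 + config.hr_jitter_pct / 100.0 * z)
        beats = np.concatenate([[beats[0]], beats[0] + np.cumsum(ibis)])
        beats = beats[beats < config.duration_s]
    return beats


def _artifact_events(config: SyntheticConfig) -> np.ndarray:
    """Artifact burst onset times (seconds), from the dedicated substream."""
    n_events = int(round(config.artifact_rate_per_min * config.duration_s / 60.0))
    if n_events == 0:
        return np.array([])
    rng = config._rng(_ARTIFACTS)
    latest = max(0.0, config.duration_s - config.artifact_duration_s)
    return np.sort(rng.uniform(0.0, latest, n_events))


def generate(config: SyntheticConfig) -> tuple[SampledSignal, BeatReference]:
    """Synthesise a PPG record and its exact ground-truth beat times."""
    n = int(round(config.duration_s * config.fs))
    t = np.arange(n) / config.fs
    x = np.full(n, float(config.baseline))

    # cardiac pulses: systolic + dicrotic Gaussian per beat, local windows
    beats = _beat_times(config)
    sd_sys = config.pulse_width_s
    sd_dic = 1.5 * sd_sys
    half = 4 * sd_dic + config.dicrotic_delay_s
    for tb in beats:
        i0 = max(0, int((tb - half) * config.fs))
        i1 = min(n, int((tb + half) * config.fs) + 1)
        tt = t[i0:i1]
        x[i0:i1] += np.exp(-((tt - tb) ** 2) / (2 * sd_sys**2))
        x[i0:i1] += config.dicrotic_frac * np.exp(
            -((tt - tb - config.dicrotic_delay_s) ** 2) / (2 * sd_dic**2)
        )

    # baseline wander: three random-phase sinusoids inside the wander band
    if config.wander_amp > 0:
        rng = config._rng(_WANDER)
        freqs = rng.uniform(*config.wander_band, 3)
        phases = rng.uniform(0, 2 * np.pi, 3)
        for f, ph in zip(freqs, phases):
            x += (config.wander_amp / 3.0) * np.sin(2 * np.pi * f * t + ph)

    # motion artifacts: smooth Hann bursts at random onsets
    onsets = _artifact_events(config)
    burst_len = int(round(config.artifact_duration_s * config.fs))
    burst = config.artifact_amp * hann(burst_len)
    for onset in onsets:
        i0 = int(round(onset * config.fs))
        i1 = min(n, i0 + burst_len)
        x[i0:i1] += burst[: i1 - i0]

    # broadband sensor noise
    if config.noise_sd > 0:
        x += config._rng(_NOISE).normal(0.0, config.noise_sd, n)

    return SampledSignal(x, fs=config.fs), BeatReference(beat_times=beats)


def artifact_mask(config: SyntheticConfig) -> np.ndarray:
    """Boolean per-sample mask, True inside every artifact burst.

    Regenerated from the config's own artifact substream, so it matches
    the bursts injected by :func:`generate` for the same config/seed
    without re-synthesising the signal.
    """
    n = int(round(config.duration_s * config.fs))
    mask = np.zeros(n, dtype=bool)
    burst_len = int(round(config.artifact_duration_s * config.fs))
    for onset in _artifact_events(config):
        i0 = int(round(onset * config.fs))
        mask[i0 : min(n, i0 + burst_len)] = True
    return mask
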