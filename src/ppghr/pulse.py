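"""Pulse-peak detection and sliding-window heart-rate estimation.

Peaks are found by greedy iteration on the decoupled cardiac signal: take
the tallest remaining sample, suppress a refractory neighbourhood around
it, and repeat until no considerable peak remains. Heart rate in bpm is the
count of detected peaks inside a sliding one-minute epoch advanced by 30 s
(50% overlap).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from ppghr.signal_io import SampledSignal

__all__ = ["PeakList", "HRSeries", "detect_peaks", "hr_sliding"]


@dataclass(frozen=True)
class PeakList:
    """Detected pulse peaks, sorted by time."""

    peak_indices: np.ndarray  # sample indices, strictly increasing
    peak_times: np.ndarray  # seconds
    amplitudes: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        idx = np.asarray(self.peak_indices, dtype=int)
        if idx.size > 1 and not np.all(np.diff(idx) > 0):
            raise ValueError("peak indices must be strictly increasing")
        object.__setattr__(self, "peak_indices", idx)
        object.__setattr__(self, "peak_times", np.asarray(self.peak_times, dtype=float))
        object.__setattr__(self, "amplitudes", np.asarray(self.amplitudes, dtype=float))

    def __len__(self) -> int:
        return self.peak_indices.size


@dataclass(frozen=True)
class HRSeries:
    """Epoch-wise heart rate: one bpm value per sliding window."""

    epoch_centers: np.ndarray  # seconds
    bpm: np.ndarray
    window_s: float
    hop_s: float

    def __post_init__(self) -> None:
        c = np.asarray(self.epoch_centers, dtype=float)
        b = np.asarray(self.bpm, dtype=float)
        if c.shape != b.shape:
            raise ValueError("epoch_centers and bpm must have the same shape")
        if np.any(b < 0):
            raise ValueError("bpm must be non-negative")
        if c.size > 1 and not np.allclose(np.diff(c), self.hop_s):
            raise ValueError("epoch centers must be evenly spaced by hop_s")
        object.__setattr__(self, "epoch_centers", c)
        object.__setattr__(self, "bpm", b)

    def __len__(self) -> int:
        return self.bpm.size

    def to_json(self) -> str:
        import json

        return json.dumps(
            {
                "window_s": self.window_s,
                "hop_s": self.hop_s,
                "epoch_centers_s": self.epoch_centers.tolist(),
                "bpm": self.bpm.tolist(),
            }
        )

    def same_grid(self, other: "HRSeries", tol: float = 1e-9) -> bool:
        return (
            len(self) == len(other)
            and np.allclose(self.epoch_centers, other.epoch_centers, atol=tol)
        )


def detect_peaks(
    cardiac: SampledSignal,
    refractory_s: float = 0.27,
    prominence_frac: float = 0.30,
) -> PeakList:
    """Iterative tallest-peak detection with a physiological refractory period.

    Greedy loop: select the global maximum of the remaining samples, mask
    ``±refractory_s`` around it, repeat. Iteration stops when the next
    candidate's amplitude falls below ``prominence_frac`` times the median
    amplitude of the peaks accepted so far (or is non-positive) — the
    "considerable peaks" cut-off. Ties go to the earlier sample. The
    default refractory period of 0.27 s bounds the detectable rate at
    ≈220 bpm, above any plausible pig heart rate.
    """
    if not (0 < refractory_s < 2):
        raise ValueError("refractory_s must lie in (0, 2) seconds")
    x = cardiac.values
    if np.ptp(x) == 0:
        warnings.warn("constant signal: no peaks detected", stacklevel=2)
        empty = np.array([], dtype=float)
        return PeakList(np.array([], dtype=int), empty, empty, cardiac.fs)

    r = max(1, round(refractory_s * cardiac.fs))
    work = x.astype(float, copy=True)
    accepted_idx: list[int] = []
    accepted_amp: list[float] = []
    while True:
        i = int(np.argmax(work))  # first occurrence wins a tie
        amp = work[i]
        if not np.isfinite(amp) or amp <= 0:
            break
        if accepted_amp and amp < prominence_frac * float(np.median(accepted_amp)):
            break
        accepted_idx.append(i)
        accepted_amp.append(float(x[i]))
        work[max(0, i - r) : i + r + 1] = -np.inf
    order = np.argsort(accepted_idx)
    idx = np.asarray(accepted_idx, dtype=int)[order]
    amps = np.asarray(accepted_amp, dtype=float)[order]
    return PeakList(idx, cardiac.t0 + idx / cardiac.fs, amps, cardiac.fs)


def hr_sliding(
    peaks: PeakList,
    total_duration_s: float,
    window_s: float = 60.0,
    hop_s: float = 30.0,
    t0: float = 0.0,
    method: str = "count",
) -> HRSeries:
    """Heart rate per sliding epoch from detected peaks.

    ``method="count"`` (default): bpm for epoch ``[t, t+window_s)`` is the
    number of peaks inside the half-open window times ``60/window_s`` — for
    the default one-minute window the count IS the bpm.
    ``method="interval"``: bpm = 60 / mean inter-peak interval inside the
    window (0 when fewer than two peaks fall in it).

    Epochs exist only where a full window fits:
    ``floor((total_duration_s − window_s)/hop_s) + 1`` of them.
    """
    if not (window_s > hop_s > 0):
        raise ValueError("require window_s > hop_s > 0")
    if total_duration_s < window_s:
        raise ValueError(
            f"recording of {total_duration_s}s is shorter than one {window_s}-s window"
        )
    n_epochs = int(np.floor((total_duration_s - window_s) / hop_s)) + 1
    starts = t0 + hop_s * np.arange(n_epochs)
    times = peaks.peak_times
    bpm = np.empty(n_epochs)
    for j, start in enumerate(starts):
        in_win = times[(times >= start) & (times < start + window_s)]
        if method == "count":
            bpm[j] = in_win.size * (60.0 / window_s)
        elif method == "interval":
            bpm[j] = 60.0 / np.mean(np.diff(in_win)) if in_win.size >= 2 else 0.0
        else:
            raise ValueError(f"unknown method {method!r}; use 'count' or 'interval'")
    return HRSeries(starts + window_s / 2, bpm, window_s, hop_s)
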