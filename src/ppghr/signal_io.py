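"""Core time-series containers, segmentation and plain-text I/O.

Conventions: sample ``n`` occurs at ``t0 + n/fs``; all indices are 0-based;
time windows are half-open ``[start, end)``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SampledSignal",
    "Segment",
    "BeatReference",
    "read_signal",
    "write_signal",
    "segment_signal",
]


@dataclass(frozen=True)
class SampledSignal:
    """A uniformly sampled real-valued time series.

    Parameters
    ----------
    values : array-like
        Sample amplitudes in arbitrary units; must be finite.
    fs : float
        Sampling rate in Hz (> 0).
    t0 : float, optional
        Time of the first sample in seconds (default 0).
    """

    values: np.ndarray
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 1 or values.size < 1:
            raise ValueError("signal must be a 1-D array with at least one sample")
        if not np.all(np.isfinite(values)):
            bad = np.flatnonzero(~np.isfinite(values))
            raise ValueError(f"non-finite samples at indices {bad[:10].tolist()}")
        if not (self.fs > 0):
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        object.__setattr__(self, "values", values)

    def __len__(self) -> int:
        return self.values.size

    @property
    def dt(self) -> float:
        """Sampling period in seconds."""
        return 1.0 / self.fs

    @property
    def duration_s(self) -> float:
        """Record duration in seconds (N samples span N/fs)."""
        return len(self) / self.fs

    @property
    def times(self) -> np.ndarray:
        """Sample times ``t0 + n/fs`` in seconds."""
        return self.t0 + np.arange(len(self)) / self.fs

    def with_values(self, values: np.ndarray) -> "SampledSignal":
        """Return a copy carrying new sample values with the same fs and t0."""
        return SampledSignal(values=np.asarray(values, dtype=float), fs=self.fs, t0=self.t0)


@dataclass(frozen=True)
class Segment:
    """One fixed-duration slice of a longer recording."""

    signal: SampledSignal
    index: int
    duration_s: float

    def __post_init__(self) -> None:
        if not (self.duration_s > 0):
            raise ValueError("duration_s must be positive")
        expected = round(self.duration_s * self.signal.fs)
        if len(self.signal) != expected:
            raise ValueError(
                f"segment length {len(self.signal)} != round(duration*fs) = {expected}"
            )


@dataclass(frozen=True)
class BeatReference:
    """Ground-truth cardiac timing: beat instants and/or an HR time series.

    Either ``beat_times`` (strictly increasing beat instants in seconds) or
    ``hr_series`` (``(time_s, bpm)`` pairs, e.g. from an ECG monitor) must be
    given; both may be.
    """

    beat_times: np.ndarray | None = None
    hr_series: np.ndarray | None = None  # shape (n, 2): time_s, bpm

    def __post_init__(self) -> None:
        if self.beat_times is None and self.hr_series is None:
            raise ValueError("provide beat_times or hr_series")
        if self.beat_times is not None:
            bt = np.asarray(self.beat_times, dtype=float)
            if bt.ndim != 1:
                raise ValueError("beat_times must be 1-D")
            if bt.size > 1 and not np.all(np.diff(bt) > 0):
                raise ValueError("beat_times must be strictly increasing")
            object.__setattr__(self, "beat_times", bt)
        if self.hr_series is not None:
            hs = np.asarray(self.hr_series, dtype=float)
            if hs.ndim != 2 or hs.shape[1] != 2:
                raise ValueError("hr_series must have shape (n, 2): time_s, bpm")
            if np.any((hs[:, 1] <= 0) | (hs[:, 1] >= 400)):
                raise ValueError("bpm values must lie in (0, 400)")
            object.__setattr__(self, "hr_series", hs)

    @property
    def end_time(self) -> float:
        ends = []
        if self.beat_times is not None and self.beat_times.size:
            ends.append(float(self.beat_times[-1]))
        if self.hr_series is not None and self.hr_series.size:
            ends.append(float(self.hr_series[-1, 0]))
        return max(ends) if ends else 0.0


def read_signal(path, fs: float, *, column: int | None = None, t0: float = 0.0) -> SampledSignal:
    """Read a PPG amplitude series from a one- or two-column CSV file.

    A single column is taken as amplitude; with two columns the first is
    assumed to be time (or sample index) and the second amplitude, unless
    ``column`` selects the amplitude column explicitly. An optional header
    row is tolerated. Non-numeric or non-finite rows abort with the
    offending row numbers.
    """
    try:
        df = pd.read_csv(path, header=None, comment="#", skip_blank_lines=True,
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        raise ValueError(f"no samples in {path}") from None
    except FileNotFoundError:
        raise FileNotFoundError(f"input file not found: {path}") from None

    # Tolerate a header line of non-numeric labels.
    first = df.iloc[0]
    if any(pd.to_numeric(first, errors="coerce").isna()):
        df = df.iloc[1:].reset_index(drop=True)
    if df.empty:
        raise ValueError(f"no samples in {path}")

    if column is None:
        column = df.shape[1] - 1 if df.shape[1] >= 2 else 0
    series = df.iloc[:, column]
    if series.dtype == object:
        # parse with Python's correctly-rounded float so values round-trip
        def _to_float(v):
            try:
                return float(v)
            except (TypeError, ValueError):
                return np.nan

        col = series.map(_to_float)
    else:
        col = series.astype(float)
    bad = col.index[~np.isfinite(col.to_numpy(dtype=float))]
    if len(bad):
        raise ValueError(
            f"non-numeric or non-finite samples at rows {list(bad[:10])} of {path}"
        )
    return SampledSignal(values=col.to_numpy(dtype=float), fs=fs, t0=t0)


def write_signal(signal: SampledSignal, path, *, include_time: bool = True) -> None:
    """Write a signal as CSV (``time_s,amplitude`` or a single amplitude column).

    Uses repr-exact float formatting so a read/write round trip preserves
    sample values to full precision.
    """
    if include_time:
        df = pd.DataFrame({"time_s": signal.times, "amplitude": signal.values})
    else:
        df = pd.DataFrame({"amplitude": signal.values})
    # 17 significant digits round-trips float64 exactly
    df.to_csv(path, index=False, float_format="%.17g")


def segment_signal(signal: SampledSignal, duration_s: float = 60.0) -> list[Segment]:
    """Split a recording into consecutive non-overlapping fixed-length segments.

    The trailing remainder shorter than ``duration_s`` is dropped (and
    logged). Raises if the recording is shorter than one segment.
    """
    if not (duration_s > 0):
        raise ValueError("duration_s must be positive")
    seg_len = round(duration_s * signal.fs)
    n = len(signal)
    if n < seg_len:
        raise ValueError(
            f"signal of {n} samples is shorter than one {duration_s}-s segment ({seg_len} samples)"
        )
    n_seg = n // seg_len
    dropped = n - n_seg * seg_len
    if dropped:
        logger.info("segment_signal: dropping trailing %d samples (%.2f s)", dropped, dropped / signal.fs)
    out = []
    for i in range(n_seg):
        sl = signal.values[i * seg_len : (i + 1) * seg_len]
        out.append(
            Segment(
                signal=SampledSignal(sl, fs=signal.fs, t0=signal.t0 + i * seg_len / signal.fs),
                index=i,
                duration_s=duration_s,
            )
        )
    return out
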