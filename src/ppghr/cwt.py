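"""Continuous wavelet transform via FFT with derivative-of-Gaussian wavelets.

The CWT of a signal x(t) at scale s and position b is the convolution

    C(s, b) = ∫ x(t) (1/√s) ψ*((t − b)/s) dt,

computed here on the Fourier side: multiply the signal's DFT by the scaled
wavelet's (conjugated) Fourier transform and invert — one FFT pair per scale
instead of N convolutions, which is what makes the transform fast enough for
real-time pulse monitoring.

The mother wavelets are m-th derivatives of a Gaussian (DOG), defined in the
Fourier domain as

    ψ̂(sω) = (1/√Γ(m + ½)) (i·s·ω)^m exp(−(sω)²/2).

Even orders are symmetric and real in the Fourier domain (m = 2 is the
Mexican hat); they concentrate the scalogram's energy on the cardiac band of
a PPG signal, which is why even m ∈ {2, 4, 6} are the supported default.
Each scaled wavelet is renormalised by √(2πs/Δt) so every scale carries unit
energy and coefficient magnitudes are comparable across scales.

A direct O(N²) quadrature of the convolution integral (``cwt_direct``),
built on the closed-form time-domain DOG via Hermite polynomials, serves as
an independent oracle for the FFT route in the test suite.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.polynomial import hermite_e
from scipy.special import gamma

from ppghr.signal_io import SampledSignal

__all__ = [
    "WaveletSpec",
    "ScaleSet",
    "CWTResult",
    "dog_fourier",
    "dog_time",
    "cwtft",
    "cwt_direct",
    "scale_energy",
    "reconstruct_cardiac",
]

#: Physiological cardiac band for pigs, Hz (≈48–200 bpm).
CARDIAC_BAND_HZ = (0.8, 3.3)


@dataclass(frozen=True)
class WaveletSpec:
    """Derivative-of-Gaussian mother wavelet of order m.

    Even orders (2, 4, 6) are the supported default: they are real and
    symmetric, so a cardiac pulse maps onto a single positive coefficient
    maximum per beat. Odd orders are accepted only with ``strict=False``.
    """

    order: int = 4
    strict: bool = True

    def __post_init__(self) -> None:
        if self.order < 1:
            raise ValueError("wavelet order must be >= 1")
        if self.strict and self.order not in (2, 4, 6):
            raise ValueError(
                f"order {self.order} not in the supported even set {{2, 4, 6}}; "
                "pass strict=False to experiment with other orders"
            )

    def center_frequency(self, scale: float) -> float:
        """Peak frequency in Hz of the scaled wavelet: √m/(2πs)."""
        return np.sqrt(self.order) / (2 * np.pi * scale)

    def scale_for_frequency(self, freq_hz: float) -> float:
        """Scale in seconds whose wavelet peaks at ``freq_hz``."""
        return np.sqrt(self.order) / (2 * np.pi * freq_hz)


@dataclass(frozen=True)
class ScaleSet:
    """Strictly increasing positive wavelet scales, in seconds."""

    scales: np.ndarray

    def __post_init__(self) -> None:
        s = np.atleast_1d(np.asarray(self.scales, dtype=float))
        if np.any(s <= 0):
            raise ValueError("scales must be positive")
        if s.size > 1 and not np.all(np.diff(s) > 0):
            raise ValueError("scales must be strictly increasing")
        object.__setattr__(self, "scales", s)

    def __len__(self) -> int:
        return self.scales.size

    @classmethod
    def from_exponents(cls, exponents, base_scale: float = 1.0) -> "ScaleSet":
        """Scales as powers of two, s = base_scale · 2^a."""
        return cls(scales=base_scale * 2.0 ** np.asarray(exponents, dtype=float))

    @classmethod
    def for_band(
        cls,
        f_lo: float = CARDIAC_BAND_HZ[0],
        f_hi: float = CARDIAC_BAND_HZ[1],
        wavelet: WaveletSpec | None = None,
        n_scales: int = 5,
    ) -> "ScaleSet":
        """Log-spaced scales whose center frequencies span ``[f_lo, f_hi]`` Hz.

        This is the default scale selection: the set covers the expected
        pulse-rate band so that the scalogram's cardiac energy is captured.
        """
        if not (0 < f_lo < f_hi):
            raise ValueError("need 0 < f_lo < f_hi")
        wavelet = wavelet or WaveletSpec()
        s_lo = wavelet.scale_for_frequency(f_hi)  # high freq -> small scale
        s_hi = wavelet.scale_for_frequency(f_lo)
        return cls(scales=np.geomspace(s_lo, s_hi, n_scales))


@dataclass(frozen=True)
class CWTResult:
    """CWT coefficients over (scale, position) with provenance."""

    coeffs: np.ndarray  # complex, (n_scales, N)
    scales: ScaleSet
    wavelet: WaveletSpec
    fs: float
    t0: float = 0.0

    def __post_init__(self) -> None:
        c = np.asarray(self.coeffs)
        if c.ndim != 2 or c.shape[0] != len(self.scales):
            raise ValueError("coeffs must be (n_scales, N)")
        if not np.all(np.isfinite(c)):
            raise ValueError("non-finite CWT coefficients")
        object.__setattr__(self, "coeffs", c)

    @property
    def n_samples(self) -> int:
        return self.coeffs.shape[1]


def dog_fourier(omega: np.ndarray, s: float, m: int) -> np.ndarray:
    """Fourier-domain DOG wavelet ψ̂(sω), elementwise over angular frequency.

    ψ̂(sω) = (1/√Γ(m+½)) (i·sω)^m exp(−(sω)²/2). Real for even m, purely
    imaginary for odd m; vanishes at ω = 0 and its magnitude peaks at
    |sω| = √m.
    """
    if s <= 0:
        raise ValueError("scale must be positive")
    if m < 1:
        raise ValueError("order must be >= 1")
    so = s * np.asarray(omega, dtype=float)
    return (1j * so) ** m * np.exp(-(so**2) / 2) / np.sqrt(gamma(m + 0.5))


def dog_time(t: np.ndarray, m: int) -> np.ndarray:
    """Time-domain DOG mother wavelet (closed form, unit scale).

    Inverse Fourier transform of ``dog_fourier``:
    ψ(t) = (−1)^m He_m(t) e^(−t²/2) / √(2π Γ(m+½)) with He_m the
    probabilists' Hermite polynomial. Real for every order; used by the
    direct-quadrature oracle.
    """
    t = np.asarray(t, dtype=float)
    he = hermite_e.hermeval(t, [0] * m + [1])
    return (-1) ** m * he * np.exp(-(t**2) / 2) / np.sqrt(2 * np.pi * gamma(m + 0.5))


def _scale_norm(s: float, dt: float) -> float:
    # unit-energy renormalisation per scale
    return np.sqrt(2 * np.pi * s / dt)


def cwtft(signal: SampledSignal, scales: ScaleSet, wavelet: WaveletSpec | None = None) -> CWTResult:
    """FFT-route CWT: per scale, invert DFT(x)·ψ̂*(sω)·√(2πs/Δt).

    The DFT length equals the signal length (no zero padding), so edge
    effects are circular; analysis segments are long relative to the
    wavelet support, which keeps them negligible away from the borders.
    DFT bins above N/2 are mapped to negative angular frequencies before
    evaluating the wavelet, preserving conjugate symmetry (real
    coefficients for real signals).
    """
    wavelet = wavelet or WaveletSpec()
    x = signal.values
    n = x.size
    if n < 8:
        raise ValueError("signal too short for CWT (need >= 8 samples)")
    xhat = np.fft.fft(x)
    omega = 2 * np.pi * np.fft.fftfreq(n, d=signal.dt)  # rad/s, signed
    coeffs = np.empty((len(scales), n), dtype=complex)
    for j, s in enumerate(scales.scales):
        psi_hat = dog_fourier(omega, s, wavelet.order) * _scale_norm(s, signal.dt)
        coeffs[j] = np.fft.ifft(xhat * np.conj(psi_hat))
    return CWTResult(coeffs=coeffs, scales=scales, wavelet=wavelet, fs=signal.fs, t0=signal.t0)


def cwt_direct(signal: SampledSignal, scales: ScaleSet, wavelet: WaveletSpec | None = None) -> CWTResult:
    """Direct quadrature of the CWT convolution integral (test oracle).

    Evaluates C(s,b) = √(2π/Δt) · Σ_n x(n) (1/√s) ψ((nΔt − bΔt)/s) Δt with
    the closed-form time-domain wavelet, sharing only the normalisation
    constant with the FFT route. O(N²) per scale — intended for N ≲ 2048.
    Linear (not circular) convolution, so the two routes agree away from
    the record edges.
    """
    wavelet = wavelet or WaveletSpec()
    x = signal.values
    n = x.size
    dt = signal.dt
    t = np.arange(n) * dt
    lag = t[None, :] - t[:, None]  # (b, n): t_n - t_b
    coeffs = np.empty((len(scales), n), dtype=complex)
    for j, s in enumerate(scales.scales):
        psi = dog_time(lag / s, wavelet.order)
        coeffs[j] = np.sqrt(2 * np.pi / dt) * (psi @ x) * dt / np.sqrt(s)
    return CWTResult(coeffs=coeffs, scales=scales, wavelet=wavelet, fs=signal.fs, t0=signal.t0)


def scale_energy(result: CWTResult) -> tuple[np.ndarray, np.ndarray]:
    """Per-scale scalogram energy Σ_b |C(s,b)|² and normalised fractions.

    For an all-zero coefficient matrix the fractions are undefined; they
    are returned uniform with a warning.
    """
    energy = np.sum(np.abs(result.coeffs) ** 2, axis=1)
    total = energy.sum()
    if total == 0:
        warnings.warn("zero scalogram energy; returning uniform fractions", stacklevel=2)
        fractions = np.full_like(energy, 1.0 / energy.size)
    else:
        fractions = energy / total
    return energy, fractions


def export_scalogram(result: CWTResult, path) -> None:
    """Write |coefficients| as a CSV matrix (one row per scale, columns = time).

    The first column holds the scale in seconds; the header row carries the
    sample times.
    """
    import pandas as pd

    times = result.t0 + np.arange(result.n_samples) / result.fs
    df = pd.DataFrame(np.abs(result.coeffs), index=result.scales.scales, columns=times)
    df.index.name = "scale_s"
    df.to_csv(path)


def reconstruct_cardiac(result: CWTResult, mode: str = "sum") -> SampledSignal:
    """Collapse multi-scale coefficients into one cardiac pulse signal.

    ``"sum"`` (default) takes the real part of the column-wise sum across
    scales — a band-limited approximation of the inverse CWT over the
    retained cardiac band, robust when the pulse frequency drifts between
    scales. ``"max_energy"`` keeps only the single highest-energy scale's
    row.
    """
    if mode == "sum":
        y = result.coeffs.sum(axis=0).real
    elif mode == "max_energy":
        energy, _ = scale_energy(result)
        y = result.coeffs[int(np.argmax(energy))].real
    else:
        raise ValueError(f"unknown reconstruction mode {mode!r}; use 'sum' or 'max_energy'")
    return SampledSignal(values=y, fs=result.fs, t0=result.t0)
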