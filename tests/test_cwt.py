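import numpy as np
import pytest
from scipy.special import gamma

from ppghr import (
    CWTResult,
    SampledSignal,
    ScaleSet,
    WaveletSpec,
    cwt_direct,
    cwtft,
    dog_fourier,
    dog_time,
    reconstruct_cardiac,
    scale_energy,
)
from ppghr.cwt import _scale_norm


def oracle_scales():
    # a few samples per oscillation and supports well inside a 256-point record
    return ScaleSet(np.geomspace(2.0, 8.0, 5))


class TestDogFourier:
    def test_vanishes_at_zero_frequency(self):
        assert dog_fourier(np.array([0.0]), s=1.3, m=4)[0] == 0

    @pytest.mark.parametrize("m,s", [(2, 1.0), (4, 1.0), (4, 0.5), (6, 2.0)])
    def test_magnitude_peaks_at_sqrt_m_over_s(self, m, s):
        omega = np.linspace(0.01, 10.0 / s, 20000)
        mag = np.abs(dog_fourier(omega, s, m))
        assert omega[np.argmax(mag)] == pytest.approx(np.sqrt(m) / s, rel=1e-3)

    def test_parity_of_orders(self):
        omega = np.linspace(-4, 4, 31)
        even = dog_fourier(omega, 1.0, 4)
        odd = dog_fourier(omega, 1.0, 3)
        assert np.allclose(even.imag, 0)
        assert np.allclose(odd.real, 0)

    def test_invalid_args(self):
        with pytest.raises(ValueError):
            dog_fourier(np.array([1.0]), s=-1.0, m=4)
        with pytest.raises(ValueError):
            dog_fourier(np.array([1.0]), s=1.0, m=0)


class TestDogTime:
    def test_mexican_hat_closed_form(self):
        # m=2: psi(t) = (t^2-1) e^{-t^2/2} / sqrt(2*pi*Gamma(5/2))
        t = np.linspace(-5, 5, 101)
        expected = (t**2 - 1) * np.exp(-(t**2) / 2) / np.sqrt(2 * np.pi * gamma(2.5))
        np.testing.assert_allclose(dog_time(t, 2), expected, atol=1e-12)

    @pytest.mark.parametrize("m", [2, 3, 4, 6])
    def test_matches_inverse_dft_of_fourier_form(self, m):
        # sample the Fourier-domain definition densely and invert numerically
        n, dt = 4096, 0.05
        omega = 2 * np.pi * np.fft.fftfreq(n, d=dt)
        psi_hat = dog_fourier(omega, 1.0, m)
        psi = np.fft.ifft(psi_hat).real / dt
        t = np.fft.fftfreq(n, d=1.0 / (n * dt))
        np.testing.assert_allclose(psi, dog_time(t, m), atol=1e-10)


class TestCwtft:
    def test_zero_signal_gives_zero(self):
        sig = SampledSignal(np.zeros(64), fs=1.0)
        assert np.all(cwtft(sig, oracle_scales()).coeffs == 0)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        x = rng.standard_normal(256)
        y = rng.standard_normal(256)
        a, b = 1.7, -0.3
        s = oracle_scales()
        lhs = cwtft(SampledSignal(a * x + b * y, fs=1.0), s).coeffs
        rhs = a * cwtft(SampledSignal(x, fs=1.0), s).coeffs + b * cwtft(SampledSignal(y, fs=1.0), s).coeffs
        assert np.max(np.abs(lhs - rhs)) < 1e-9

    @pytest.mark.parametrize("m", [2, 4, 6])
    def test_oracle_equivalence_central_samples(self, m):
        rng = np.random.default_rng(42)
        sig = SampledSignal(rng.standard_normal(256), fs=1.0)
        s = oracle_scales()
        w = WaveletSpec(order=m)
        fast = cwtft(sig, s, w).coeffs
        direct = cwt_direct(sig, s, w).coeffs
        central = slice(64, 192)
        err = np.max(np.abs(fast[:, central] - direct[:, central]))
        assert err < 0.01 * np.max(np.abs(fast))

    def test_shift_covariance(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(256)
        s = oracle_scales()
        d = 37
        base = cwtft(SampledSignal(x, fs=1.0), s).coeffs
        shifted = cwtft(SampledSignal(np.roll(x, d), fs=1.0), s).coeffs
        np.testing.assert_allclose(np.roll(base, d, axis=1), shifted, atol=1e-9)

    def test_even_order_real_coefficients(self):
        rng = np.random.default_rng(3)
        sig = SampledSignal(rng.standard_normal(512), fs=1.0)
        c = cwtft(sig, oracle_scales(), WaveletSpec(order=4)).coeffs
        assert np.max(np.abs(c.imag)) < 1e-9 * np.max(np.abs(c))

    def test_unit_energy_per_scale(self):
        # with the sqrt(2*pi*s/dt) factor, sum_k |psi_hat|^2 is scale-invariant
        n, fs = 7680, 128.0
        omega = 2 * np.pi * np.fft.fftfreq(n, d=1 / fs)
        energies = []
        for s in ScaleSet.for_band().scales:
            psi_hat = dog_fourier(omega, s, 4) * _scale_norm(s, 1 / fs)
            energies.append(np.sum(np.abs(psi_hat) ** 2))
        energies = np.asarray(energies)
        assert energies.max() / energies.min() - 1 < 0.02

    def test_too_short_signal(self):
        with pytest.raises(ValueError):
            cwtft(SampledSignal(np.ones(4), fs=1.0), oracle_scales())


class TestCwtDirect:
    def test_impulse_reproduces_wavelet_shape(self):
        n = 256
        x = np.zeros(n)
        x[n // 2] = 1.0
        sig = SampledSignal(x, fs=1.0)
        s = 4.0
        row = cwt_direct(sig, ScaleSet(np.array([s])), WaveletSpec(4)).coeffs[0].real
        b = np.arange(n)
        expected = np.sqrt(2 * np.pi) / np.sqrt(s) * dog_time((n // 2 - b) / s, 4)
        np.testing.assert_allclose(row, expected, atol=1e-12)

    def test_zero_signal(self):
        sig = SampledSignal(np.zeros(64), fs=1.0)
        assert np.all(cwt_direct(sig, oracle_scales()).coeffs == 0)


class TestScaleSet:
    def test_validation(self):
        with pytest.raises(ValueError):
            ScaleSet(np.array([1.0, 0.5]))
        with pytest.raises(ValueError):
            ScaleSet(np.array([-1.0]))

    def test_from_exponents_power_of_two(self):
        ss = ScaleSet.from_exponents([0.16, 0.21, 0.28, 0.38, 0.50])
        np.testing.assert_allclose(ss.scales, 2.0 ** np.array([0.16, 0.21, 0.28, 0.38, 0.50]))

    def test_band_scales_map_to_requested_frequencies(self):
        w = WaveletSpec(order=4)
        ss = ScaleSet.for_band(0.8, 3.3, wavelet=w)
        assert w.center_frequency(ss.scales[0]) == pytest.approx(3.3)
        assert w.center_frequency(ss.scales[-1]) == pytest.approx(0.8)

    def test_odd_order_requires_opt_in(self):
        with pytest.raises(ValueError, match="even"):
            WaveletSpec(order=3)
        assert WaveletSpec(order=3, strict=False).order == 3


class TestScaleEnergyAndReconstruction:
    def test_single_scale_fraction_one(self):
        sig = SampledSignal(np.random.default_rng(0).standard_normal(256), fs=1.0)
        res = cwtft(sig, ScaleSet(np.array([4.0])))
        _, frac = scale_energy(res)
        np.testing.assert_allclose(frac, [1.0])

    def test_sine_energy_peaks_at_matching_scale(self):
        fs, f = 128.0, 1.5
        t = np.arange(int(120 * fs)) / fs
        sig = SampledSignal(np.sin(2 * np.pi * f * t), fs=fs)
        w = WaveletSpec(order=4)
        scales = ScaleSet.for_band(0.5, 4.0, wavelet=w, n_scales=15)
        energy, _ = scale_energy(cwtft(sig, scales, w))
        best = scales.scales[np.argmax(energy)]
        centers = np.sqrt(4) / (2 * np.pi * scales.scales)
        # the winning scale is the one whose center frequency is nearest f
        assert best == scales.scales[np.argmin(np.abs(centers - f))]

    def test_zero_signal_uniform_fractions_with_warning(self):
        res = cwtft(SampledSignal(np.zeros(64), fs=1.0), oracle_scales())
        with pytest.warns(UserWarning, match="zero scalogram"):
            _, frac = scale_energy(res)
        np.testing.assert_allclose(frac, 0.2)

    def test_single_scale_reconstruction_modes_agree(self):
        sig = SampledSignal(np.random.default_rng(5).standard_normal(256), fs=1.0)
        res = cwtft(sig, ScaleSet(np.array([4.0])))
        row = res.coeffs[0].real
        np.testing.assert_array_equal(reconstruct_cardiac(res, "sum").values, row)
        np.testing.assert_array_equal(reconstruct_cardiac(res, "max_energy").values, row)

    def test_unknown_mode(self):
        res = cwtft(SampledSignal(np.zeros(64), fs=1.0), oracle_scales())
        with pytest.raises(ValueError, match="mode"):
            reconstruct_cardiac(res, "median")

    def test_pulse_train_reconstruction_recovers_cardiac_frequency(self):
        fs = 128.0
        t = np.arange(int(120 * fs)) / fs
        x = np.sin(2 * np.pi * 1.5 * t) + 2.0 * np.sin(2 * np.pi * 0.2 * t)
        sig = SampledSignal(x, fs=fs)
        w = WaveletSpec(order=4)
        rec = reconstruct_cardiac(cwtft(sig, ScaleSet.for_band(wavelet=w), w))
        spec = np.abs(np.fft.rfft(rec.values))
        freqs = np.fft.rfftfreq(len(rec), 1 / fs)
        assert freqs[np.argmax(spec)] == pytest.approx(1.5, abs=0.05)

    def test_scalogram_csv_export(self, tmp_path):
        import pandas as pd

        sig = SampledSignal(np.random.default_rng(2).standard_normal(128), fs=1.0)
        res = cwtft(sig, oracle_scales())
        path = tmp_path / "scalogram.csv"
        from ppghr.cwt import export_scalogram

        export_scalogram(res, path)
        back = pd.read_csv(path, index_col=0)
        assert back.shape == (5, 128)
        np.testing.assert_allclose(back.to_numpy(), np.abs(res.coeffs), rtol=1e-6)

    def test_result_validation(self):
        with pytest.raises(ValueError):
            CWTResult(coeffs=np.zeros((2, 8)), scales=ScaleSet(np.array([1.0])),
                      wavelet=WaveletSpec(4), fs=1.0)
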