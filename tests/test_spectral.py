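"""Spectral estimation: windowing arithmetic, Parseval, band power,
normalization, spectral entropy."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from lfpipe.recio import BandDef
from lfpipe.spectral import (BandPowerSeries, Spectrogram, band_power,
                             multitaper_spectrogram, normalize_power,
                             spectral_entropy, welch_psd)


class TestMultitaperSpectrogram:
    def test_bin_count_300s(self, rng):
        x = rng.standard_normal(300 * 1000)
        spec = multitaper_spectrogram(x, 1000.0, window_s=30.0, step_s=3.0)
        assert spec.times.size == 91  # floor((300-30)/3)+1
        assert np.allclose(np.diff(spec.times), 3.0)

    def test_sine_peak_location(self, rng):
        fs = 1000.0
        t = np.arange(int(120 * fs)) / fs
        x = np.sin(2 * np.pi * 6.0 * t) + 0.05 * rng.standard_normal(t.size)
        spec = multitaper_spectrogram(x, fs, window_s=30.0, step_s=3.0,
                                      band=(1.0, 60.0))
        df = spec.freqs[1] - spec.freqs[0]
        # multitaper smearing is ~NW/window = 0.1 Hz around the tone
        halfwidth = 3.0 / 30.0 + df
        peaks = spec.freqs[np.argmax(spec.power, axis=1)]
        assert np.all(np.abs(peaks - 6.0) <= halfwidth + 1e-9)

    def test_zero_signal(self):
        spec = multitaper_spectrogram(np.zeros(60_000), 1000.0)
        assert np.all(spec.power == 0)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(ValueError, match="window"):
            multitaper_spectrogram(np.zeros(1000), 1000.0, window_s=30.0)

    def test_marginal_matches_welch_shape(self, rng):
        """Averaged spectrogram bins of stationary noise correlate > 0.99
        with the Welch PSD interpolated on the same grid."""
        fs = 1000.0
        x = rng.standard_normal(int(600 * fs))
        spec = multitaper_spectrogram(x, fs, window_s=30.0, step_s=3.0,
                                      band=(1.0, 140.0))
        marg = spec.power.mean(axis=0)
        psd = welch_psd(x, fs, segment_s=30.0)
        ref = np.interp(spec.freqs, psd.freqs, psd.power)
        assert marg.mean() == pytest.approx(ref.mean(), rel=0.02)
        k = np.ones(101) / 101  # smooth out single-bin estimator variance
        sm_marg = np.convolve(marg, k, mode="valid")
        sm_ref = np.convolve(ref, k, mode="valid")
        assert np.allclose(sm_marg, sm_ref, rtol=0.05)


class TestWelch:
    def test_parseval_white_noise(self, rng):
        x = rng.standard_normal(60_000)
        psd = welch_psd(x, 1000.0)
        total = np.trapezoid(psd.power, psd.freqs)
        assert total == pytest.approx(np.var(x), rel=0.05)

    def test_sine_band_power_is_half_amplitude_squared(self):
        fs = 1000.0
        t = np.arange(int(60 * fs)) / fs
        psd = welch_psd(np.sin(2 * np.pi * 10 * t), fs)
        p = band_power(psd, BandDef("ten", 9.5, 10.5))
        assert p == pytest.approx(0.5, rel=0.05)

    def test_zero_signal(self):
        psd = welch_psd(np.zeros(10_000), 1000.0)
        assert np.all(psd.power == 0)

    def test_segment_longer_than_signal_rejected(self):
        with pytest.raises(ValueError):
            welch_psd(np.zeros(100), 1000.0, segment_s=4.0)


class TestBandPower:
    def flat_spectrum(self, density=1.0, f_max=100.0, n=513):
        freqs = np.linspace(0.0, f_max, n)
        from lfpipe.spectral import PowerSpectrum

        return PowerSpectrum(freqs=freqs, power=np.full(n, density))

    def test_rectangle_integral(self):
        assert band_power(self.flat_spectrum(), BandDef("g", 30, 60)) \
            == pytest.approx(30.0)

    def test_zero_region(self):
        spec = self.flat_spectrum()
        spec.power[:] = 0.0
        assert band_power(spec, BandDef("g", 30, 60)) == 0.0

    def test_additivity_over_partition(self, rng):
        x = rng.standard_normal(30_000)
        psd = welch_psd(x, 1000.0)
        total = band_power(psd, BandDef("full", 1, 200))
        edges = [1, 4, 12, 30, 60, 140, 200]
        parts = sum(band_power(psd, BandDef("p", lo, hi))
                    for lo, hi in zip(edges, edges[1:]))
        assert parts == pytest.approx(total, rel=1e-9)

    def test_band_outside_range_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            band_power(self.flat_spectrum(f_max=100.0), BandDef("x", 50, 150))


class TestNormalize:
    def series(self, values, step=1.0):
        values = np.asarray(values, dtype=float)
        return BandPowerSeries(times=np.arange(values.size) * step,
                               values=values, band=BandDef("b", 1, 10))

    def test_constant_series_all_ones(self):
        out = normalize_power(self.series([3.0] * 5), (0.0, 4.0))
        assert np.allclose(out.values, 1.0)

    def test_example_arithmetic(self):
        out = normalize_power(self.series([2.0, 2.0, 4.0]), (0.0, 1.0))
        assert np.allclose(out.values, [1.0, 1.0, 2.0])

    def test_baseline_mean_is_one(self, rng):
        vals = rng.uniform(0.5, 2.0, 50)
        out = normalize_power(self.series(vals), (0.0, 20.0))
        assert out.values[:21].mean() == pytest.approx(1.0)

    def test_empty_baseline_rejected(self):
        with pytest.raises(ValueError):
            normalize_power(self.series([1.0, 2.0]), (10.0, 20.0))


def spec_from_power(power):
    power = np.atleast_2d(np.asarray(power, dtype=float))
    return Spectrogram(times=np.arange(power.shape[0], dtype=float),
                       freqs=np.arange(power.shape[1], dtype=float),
                       power=power)


class TestSpectralEntropy:
    def test_flat_is_one(self):
        assert spectral_entropy(spec_from_power(np.ones(64))).values[0] \
            == pytest.approx(1.0)

    def test_single_bin_is_zero(self):
        p = np.zeros(64)
        p[10] = 5.0
        assert spectral_entropy(spec_from_power(p)).values[0] == 0.0

    def test_two_of_256_bins(self):
        p = np.zeros(256)
        p[3] = p[77] = 1.0
        assert spectral_entropy(spec_from_power(p)).values[0] \
            == pytest.approx(np.log(2) / np.log(256))

    def test_all_zero_bin_maps_to_zero(self):
        vals = spectral_entropy(spec_from_power(np.zeros(16))).values
        assert vals[0] == 0.0

    def test_single_frequency_bin_rejected(self):
        with pytest.raises(ValueError):
            spectral_entropy(spec_from_power(np.ones((3, 1))))

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(deadline=None, derandomize=True)
    def test_amplitude_invariance(self, c):
        rng = np.random.default_rng(5)
        p = rng.uniform(0.0, 1.0, (4, 32))
        a = spectral_entropy(spec_from_power(p)).values
        b = spectral_entropy(spec_from_power(c * p)).values
        assert np.allclose(a, b, atol=1e-12)

    def test_noise_above_oscillator(self):
        """SpE of white noise exceeds SpE of a strong single oscillator for
        every seed."""
        from lfpipe.synth import ModeSpec, generate_mode_epoch

        fs = 1000.0
        osc = ModeSpec("I", oscillators=((6.0, 1.0, 20.0),))
        flat = ModeSpec("I", oscillators=())
        for seed in range(10):
            rng = np.random.default_rng(seed)
            a = generate_mode_epoch(flat, 60.0, fs, rng, noise_exponent=0.0)
            b = generate_mode_epoch(osc, 60.0, fs, rng, noise_exponent=0.0)
            sa = spectral_entropy(multitaper_spectrogram(a, fs, window_s=10,
                                                         step_s=10))
            sb = spectral_entropy(multitaper_spectrogram(b, fs, window_s=10,
                                                         step_s=10))
            assert sa.values.mean() > sb.values.mean()
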