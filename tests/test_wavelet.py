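"""Morse transform: tone localization, band extraction, smoothing, crossing."""

import numpy as np
import pytest

from cbtrhythms import (
    BandPowerSeries,
    CrossingCriterion,
    TemperatureSeries,
    WaveletParams,
    WaveletSpectrum,
    band_max_power,
    crossing_time,
    morse_transform,
    normalize_power,
    smooth_power,
)
from conftest import tone_series


def time_avg_valid_power(spec):
    return np.array(
        [spec.power[spec.valid[:, j], j].mean() for j in range(spec.periods_h.size)]
    )


class TestMorseTransform:
    def test_zero_signal_zero_power(self):
        ts = TemperatureSeries("z", np.arange(3 * 1440), np.full(3 * 1440, 37.0))
        spec = morse_transform(ts, WaveletParams(period_max_h=12.0))
        assert np.allclose(spec.power, 0.0)

    def test_tone_peaks_within_one_voice_of_24h(self, tone24_spectrum):
        avg = time_avg_valid_power(tone24_spectrum)
        peak = tone24_spectrum.periods_h[np.argmax(avg)]
        voice = 2 ** (1 / 16)
        assert 24.0 / voice <= peak <= 24.0 * voice
        # FFT oracle: the dominant spectral component is indeed at 24 h
        x = np.cos(2 * np.pi * np.arange(20 * 1440) / 1440)
        freqs = np.fft.rfftfreq(x.size, d=1 / 60.0)  # cycles per hour
        k = np.argmax(np.abs(np.fft.rfft(x))[1:]) + 1
        assert 1 / freqs[k] == pytest.approx(24.0, rel=0.01)

    def test_superposition_two_band_peaks(self):
        t = np.arange(20 * 1440)
        x = 37 + np.cos(2 * np.pi * t / 1440) + 0.5 * np.cos(2 * np.pi * t / 120)
        spec = morse_transform(TemperatureSeries("2tone", t, x))
        avg = time_avg_valid_power(spec)
        per = spec.periods_h
        ur_peak = per[(per >= 1) & (per <= 3)][np.argmax(avg[(per >= 1) & (per <= 3)])]
        cr_peak = per[(per >= 23) & (per <= 25)][np.argmax(avg[(per >= 23) & (per <= 25)])]
        # each band's internal maximum is a local maximum of the full curve
        for p in (ur_peak, cr_peak):
            j = int(np.flatnonzero(per == p)[0])
            assert avg[j] >= avg[j - 1] and avg[j] >= avg[j + 1]

    def test_amplitude_doubling_quadruples_power(self):
        a = morse_transform(tone_series(24.0, 12, amplitude=1.0),
                            WaveletParams(period_min_h=12, period_max_h=39))
        b = morse_transform(tone_series(24.0, 12, amplitude=2.0),
                            WaveletParams(period_min_h=12, period_max_h=39))
        np.testing.assert_allclose(b.power, 4.0 * a.power, rtol=1e-9, atol=1e-12)

    def test_shift_covariance_in_valid_region(self):
        rng = np.random.default_rng(3)
        n = 12 * 1440
        x = 37 + np.cos(2 * np.pi * np.arange(n) / 1440) + 0.05 * rng.standard_normal(n)
        k = 600
        params = WaveletParams(period_min_h=12, period_max_h=30)
        s1 = morse_transform(TemperatureSeries("s", np.arange(n), x), params)
        s2 = morse_transform(TemperatureSeries("s", np.arange(n), np.roll(x, k)), params)
        # exclude a generous margin around the record edges and the wrap point:
        # the envelope still leaks measurably beyond its e-folding width
        from cbtrhythms.wavelet import _efold_halfwidth_periods
        w = int(3 * _efold_halfwidth_periods(5.0, 3.0) * params.period_max_h * 60)
        both = np.zeros_like(s1.valid)
        both[w + k : n - w - k] = True
        ref = s1.power[both]
        np.testing.assert_allclose(np.roll(s2.power, -k, axis=0)[both], ref,
                                   rtol=0.02, atol=1e-3 * ref.max())

    @pytest.mark.parametrize("beta,gamma", [(3.0, 2.0), (8.0, 5.0), (5.0, 3.0)])
    def test_peak_mapping_spot_checks(self, beta, gamma):
        params = WaveletParams(beta=beta, gamma=gamma, period_min_h=12.0,
                               period_max_h=39.0)
        spec = morse_transform(tone_series(24.0, 16), params)
        avg = time_avg_valid_power(spec)
        peak = spec.periods_h[np.argmax(avg)]
        voice = 2 ** (1 / params.voices_per_octave)
        assert 24.0 / voice <= peak <= 24.0 * voice

    def test_missing_values_rejected(self):
        x = np.full(5 * 1440, 37.0)
        x[10] = np.nan
        with pytest.raises(ValueError, match="missing"):
            morse_transform(TemperatureSeries("m", np.arange(x.size), x),
                            WaveletParams(period_max_h=12.0))

    def test_too_short_record_rejected(self):
        ts = tone_series(24.0, 2)
        with pytest.raises(ValueError, match="shorter"):
            morse_transform(ts)


def synthetic_spectrum(n=2000, periods=(1.5, 12.0, 24.0)):
    periods = np.array(periods)
    power = np.zeros((n, periods.size))
    valid = np.ones_like(power, dtype=bool)
    return WaveletSpectrum("syn", np.arange(n), periods, power, valid)


class TestBandMaxPower:
    def test_single_period_band_selects_row(self):
        spec = synthetic_spectrum()
        spec.power[:, 2] = 3.0
        cr = band_max_power(spec, (23, 25))
        ur = band_max_power(spec, (1, 3))
        assert np.all(cr.values == 3.0)
        assert np.all(ur.values == 0.0)

    def test_band_widening_is_monotone(self, tone24_spectrum):
        narrow = band_max_power(tone24_spectrum, (23, 25))
        wide = band_max_power(tone24_spectrum, (1, 39))
        assert np.all(wide.values >= narrow.values - 1e-15)

    def test_pure_tone_band_power_nearly_constant(self, tone24_spectrum):
        bp = band_max_power(tone24_spectrum, (23, 25))
        v = bp.values[bp.valid]
        assert np.std(v) / np.mean(v) < 0.10

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError, match="no grid periods"):
            band_max_power(synthetic_spectrum(), (40, 50))


class TestSmoothNormalize:
    def bp(self, values, valid=None):
        values = np.asarray(values, dtype=float)
        valid = np.ones(values.size, bool) if valid is None else valid
        return BandPowerSeries("a", (23, 25), np.arange(values.size), values, valid)

    def test_constant_series_unchanged(self):
        out = smooth_power(self.bp(np.full(4000, 2.5)), window_h=24)
        np.testing.assert_allclose(out.values, 2.5)

    def test_impulse_spreads_to_plateau(self):
        v = np.zeros(5000)
        v[2500] = 1.0
        out = smooth_power(self.bp(v), window_h=24)
        inside = np.abs(np.arange(5000) - 2500) <= 719
        np.testing.assert_allclose(out.values[inside], 1 / 1440)
        assert np.all(out.values[np.abs(np.arange(5000) - 2500) > 720] == 0)

    def test_repeated_smoothing_reduces_variance(self):
        rng = np.random.default_rng(4)
        once = smooth_power(self.bp(rng.random(6000)), window_h=6)
        twice = smooth_power(once, window_h=6)
        assert np.var(twice.values) <= np.var(once.values)

    def test_invalid_samples_excluded_from_mean(self):
        v = np.ones(3000)
        valid = np.ones(3000, bool)
        v[1000:1100] = 100.0
        valid[1000:1100] = False
        out = smooth_power(self.bp(v, valid), window_h=24)
        np.testing.assert_allclose(out.values[valid], 1.0)

    def test_normalize_affine_invariance(self):
        rng = np.random.default_rng(5)
        v = rng.random(2000)
        a = normalize_power(self.bp(v))
        b = normalize_power(self.bp(3.5 * v + 1.2))
        np.testing.assert_allclose(a.values, b.values, atol=1e-10)

    def test_normalize_whole_record_mean0_sd1(self):
        rng = np.random.default_rng(6)
        out = normalize_power(self.bp(rng.random(2000)))
        assert out.values.mean() == pytest.approx(0.0, abs=1e-12)
        assert out.values.std() == pytest.approx(1.0, rel=1e-12)

    def test_normalize_zero_sd_rejected(self):
        with pytest.raises(ValueError, match="zero SD"):
            normalize_power(self.bp(np.full(100, 1.0)))


class TestCrossingTime:
    def daily_bp(self, days, values):
        days = np.asarray(days)
        return BandPowerSeries("a", (23, 25), (days * 1440).astype(np.int64),
                               np.asarray(values, dtype=float),
                               np.ones(days.size, bool), smoothed=True)

    def test_never_crossing_returns_none(self):
        days = np.arange(26, 60)
        bp = self.daily_bp(days, np.full(days.size, 1.0) + 0.001 * (days % 3))
        assert crossing_time(bp, CrossingCriterion(reference_window=(26, 29))) is None

    def test_step_function_crossing_day(self):
        days = np.arange(26, 60)
        v = np.where(days >= 33, 5.0, 1.0) + 0.01 * (days % 2)
        crit = CrossingCriterion(reference_window=(26, 33))
        assert crossing_time(self.daily_bp(days, v), crit) == 33

    def test_reference_outside_record_rejected(self):
        days = np.arange(40, 60)
        with pytest.raises(ValueError, match="reference window"):
            crossing_time(self.daily_bp(days, np.ones(days.size)),
                          CrossingCriterion(reference_window=(26, 29)))
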