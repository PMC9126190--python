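"""fE2 rise detection, 4-day alignment, ovulatory metrics, FFT band AUC."""

import numpy as np
import pandas as pd
import pytest

from cbtrhythms import (
    CycleAlignment,
    HormoneSeries,
    align_cycles,
    combined_metric,
    day_of_cycle_test,
    detect_rise,
    fe2_cycle_auc,
    fft_band_auc,
    fft_dominant_period,
)


def hormone(days, values, aid="h1"):
    return HormoneSeries(aid, np.asarray(days), np.asarray(values, dtype=float))


def cycling_series(n_cycles=6, baseline=0.25, profile=(1, 2, 3, 0.5), rise_day=31):
    days = np.arange(25, rise_day + 4 * n_cycles)
    vals = np.full(days.size, baseline)
    post = days >= rise_day
    vals[post] = np.array(profile * n_cycles)[: post.sum()]
    return hormone(days, vals)


class TestDetectRise:
    def test_constant_series_undefined_threshold(self):
        det = detect_rise(hormone(np.arange(25, 50), np.full(25, 10.0)))
        assert det.rise_day is None
        assert det.undefined_threshold

    def test_hand_computed_fixture(self):
        # baseline p25-30 {10,11,9,10,10,10}: mean 10, sd 0.632 -> threshold 11.26
        days = np.arange(25, 34)
        vals = [10, 11, 9, 10, 10, 10, 11, 11, 14]
        det = detect_rise(hormone(days, vals))
        assert det.baseline_mean == pytest.approx(10.0)
        assert det.baseline_sd == pytest.approx(np.std([10, 11, 9, 10, 10, 10], ddof=1))
        assert det.rise_day == 33

    def test_incomplete_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline days"):
            detect_rise(hormone([25, 26, 27, 31, 32], [10, 10, 10, 12, 14]))

    def test_noiseless_cycle_rise_at_first_block_day(self):
        det = detect_rise(cycling_series())
        assert det.rise_day == 31


class TestAlignCycles:
    def test_rising_profile_peak_on_day3_every_block(self):
        h = cycling_series()
        det = detect_rise(h)
        align = align_cycles(h, det)
        assert align.anchor_day == det.rise_day
        assert align.peak_day_index == 3
        for window in align.complete_blocks:
            vals = h.fe2[np.isin(h.day, window)]
            assert np.argmax(vals) == 2

    def test_rotated_profile_shifts_anchor(self):
        h = cycling_series(profile=(2, 3, 0.5, 1))
        det = detect_rise(h)
        align = align_cycles(h, det)
        # peak is one day after the rise; anchor shifts so it lands on slot 3
        assert align.day_of_cycle(det.rise_day + 1) == 3
        assert align.peak_day_index == 3

    def test_single_complete_block(self):
        days = np.concatenate([np.arange(25, 31), np.arange(31, 35)])
        vals = np.concatenate([np.full(6, 0.25), [1, 2, 3, 0.5]])
        h = hormone(days, vals)
        align = align_cycles(h, detect_rise(h))
        assert len(align.complete_blocks) == 1
        np.testing.assert_array_equal(align.day_of_cycle(np.arange(31, 35)),
                                      [1, 2, 3, 4])

    def test_no_rise_rejected(self):
        h = cycling_series()
        det = detect_rise(hormone(np.arange(25, 50), np.full(25, 10.0)))
        with pytest.raises(ValueError, match="no detected rise"):
            align_cycles(h, det)


class TestCombinedMetric:
    def daily(self, cbt, ur, aid="m1"):
        return pd.DataFrame({
            "animal_id": aid, "day": np.arange(31, 31 + len(cbt)),
            "cbt_mean": cbt, "ur_power": ur,
        })

    def test_identical_profiles_cancel(self):
        v = [1.0, 3.0, 2.0, 5.0, 4.0]
        (m,) = combined_metric(self.daily(v, v))
        np.testing.assert_allclose(m.combined, 0.0, atol=1e-12)

    def test_five_day_toy_hand_computed(self):
        # CBT {37,37,38,37,37}: z day3 = 2.0; UR {2,2,1,2,2}: z day3 = -2.0
        (m,) = combined_metric(self.daily([37, 37, 38, 37, 37], [2, 2, 1, 2, 2]))
        np.testing.assert_allclose(m.combined, [-1, -1, 4, -1, -1], atol=1e-12)

    def test_affine_invariance_of_both_inputs(self):
        rng = np.random.default_rng(12)
        cbt, ur = rng.random(10), rng.random(10)
        (a,) = combined_metric(self.daily(cbt, ur))
        (b,) = combined_metric(self.daily(2.0 * cbt + 5.0, 0.3 * ur + 7.0))
        np.testing.assert_allclose(a.combined, b.combined, atol=1e-10)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            combined_metric(self.daily([37.0] * 5, [1, 2, 3, 2, 1]))


class TestDayOfCycleTest:
    def metric_frame(self, values_by_day, n_blocks, anchor=31, aid="a1", noise=0.0,
                     seed=0):
        rng = np.random.default_rng(seed)
        days = np.arange(anchor, anchor + 4 * n_blocks)
        vals = np.tile(values_by_day, n_blocks) + noise * rng.standard_normal(days.size)
        df = pd.DataFrame({"animal_id": aid, "day": days, "combined": vals})
        align = CycleAlignment(aid, 4, anchor, pd.DataFrame(), [], 3)
        return df, {aid: align}

    def test_constant_metric_null(self):
        df, aligns = self.metric_frame([1.0, 1.0, 1.0, 1.0], 5)
        res = day_of_cycle_test(df, aligns)
        assert res.p_value == pytest.approx(1.0)

    def test_day_label_determines_value(self):
        df, aligns = self.metric_frame([0.0, 0.0, 0.0, 2.0], 8, noise=0.3)
        res = day_of_cycle_test(df, aligns, always_pairwise=True)
        assert res.p_value < 0.01
        pw = res.pairwise.set_index(["group_a", "group_b"])
        # the elevated day (day 4) beats every other day
        for other in ("day1", "day2", "day3"):
            assert pw.loc[(other, "day4"), "p_adj"] < 0.05

    def test_too_few_blocks_rejected(self):
        df, aligns = self.metric_frame([0, 0, 0, 1.0], 1)
        with pytest.raises(ValueError, match="2 complete blocks"):
            day_of_cycle_test(df, aligns)


class TestFftBand:
    def test_pure_four_day_tone_peak(self):
        days = np.arange(24)
        v = 37 + np.sin(2 * np.pi * days / 4.0)
        assert fft_dominant_period(days, v) == pytest.approx(4.0, rel=0.05)

    def test_sinusoid_increases_band_auc_over_noise(self):
        days = np.arange(24)
        wins = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noise = rng.standard_normal(24)
            a = fft_band_auc(days, noise)
            b = fft_band_auc(days, noise + np.sin(2 * np.pi * days / 4.0))
            wins += b > a
        assert wins == 20

    def test_additive_over_disjoint_subbands(self):
        rng = np.random.default_rng(13)
        days = np.arange(30)
        v = rng.random(30)
        total = fft_band_auc(days, v, (4.0, 5.0))
        parts = fft_band_auc(days, v, (4.0, 4.5)) + fft_band_auc(days, v, (4.5, 5.0))
        assert total == pytest.approx(parts, rel=1e-9)
        assert total >= 0

    def test_short_span_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            fft_band_auc(np.arange(10), np.random.default_rng(0).random(10))


class TestFe2CycleAuc:
    def make_aligned(self, profile, n_cycles=3):
        h = cycling_series(n_cycles=n_cycles, profile=profile)
        return h, align_cycles(h, detect_rise(h))

    def test_hand_trapezoid(self):
        h, align = self.make_aligned((1, 2, 3, 0.5))
        auc = fe2_cycle_auc(h, align)
        # (1+2)/2 + (2+3)/2 + (3+0.5)/2 = 5.75 per complete block
        assert np.allclose(auc["auc"], 5.75)

    def test_zero_block_zero_area(self):
        days = np.arange(25, 45)
        vals = np.zeros(days.size)
        h = hormone(days, vals)
        align = CycleAlignment("h1", 4, 31, pd.DataFrame(), [np.arange(31, 35)], None)
        assert fe2_cycle_auc(h, align)["auc"].iloc[0] == 0.0

    def test_doubling_fe2_doubles_auc(self):
        h1, a1 = self.make_aligned((1, 2, 3, 0.5))
        h2 = HormoneSeries("h2", h1.day, 2.0 * h1.fe2)
        auc1 = fe2_cycle_auc(h1, a1)["auc"].to_numpy()
        auc2 = fe2_cycle_auc(h2, a1)["auc"].to_numpy()
        np.testing.assert_allclose(auc2, 2.0 * auc1)
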