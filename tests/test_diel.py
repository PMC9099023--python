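"""Average-day profiles, LD scoring, onset/offset, partitions, pulses."""

import numpy as np
import pytest

from chronobug import simulate
from chronobug.diel import (
    AverageDayProfile,
    average_day,
    circular_smooth,
    classify_ld,
    group_daily_profile,
    light_dark_partition,
    onset_offset,
    pulse_response,
)
from chronobug.schedules import ActivitySeries, LightSchedule, Pulse, make_schedule


def _series(counts, schedule, bin_minutes=5):
    return ActivitySeries("a", np.asarray(counts, dtype=float), bin_minutes, schedule)


def _profile(values, sigma_minutes=20.0, bin_minutes=5.0):
    values = np.asarray(values, dtype=float)
    grid = np.arange(len(values)) * bin_minutes
    sm = circular_smooth(values, sigma_minutes / bin_minutes)
    return AverageDayProfile(grid, values, sm, 1, sigma_minutes)


class TestAverageDay:
    def test_constant_series_gives_flat_profile(self, ld186_5d):
        s = _series(np.full(5 * 288, 4.0), ld186_5d)
        prof = average_day(s, 5)
        np.testing.assert_allclose(prof.raw_mean, 4.0)
        np.testing.assert_allclose(prof.smoothed, 4.0, rtol=1e-12)

    def test_daily_spike_smooths_to_gaussian_bump(self, ld186_5d):
        counts = np.zeros(5 * 288)
        spike_bin = 8 * 12  # ZT8
        counts[spike_bin::288] = 10.0
        prof = average_day(_series(counts, ld186_5d), 5, sigma_minutes=20.0)
        # closed form: delta convolved with the wrapped Gaussian kernel
        d = np.minimum(np.abs(np.arange(288) - spike_bin), 288 - np.abs(np.arange(288) - spike_bin))
        kernel = np.exp(-0.5 * (d / 4.0) ** 2)
        expected = 10.0 * kernel / kernel.sum()
        np.testing.assert_allclose(prof.smoothed, expected, atol=1e-9)
        assert int(np.argmax(prof.smoothed)) == spike_bin

    def test_window_longer_than_series_rejected(self, ld186_5d):
        s = _series(np.zeros(3 * 288), ld186_5d)
        with pytest.raises(ValueError):
            average_day(s, 5)

    def test_smoothing_conserves_sum(self, ld186_5d, rng):
        s = _series(rng.poisson(3.0, 5 * 288), ld186_5d)
        prof = average_day(s, 5)
        assert prof.smoothed.sum() == pytest.approx(prof.raw_mean.sum(), rel=1e-9)


class TestClassifyLD:
    def test_wt_agent_rhythmic_with_midday_peak(self, ld186_5d):
        s = simulate.simulate_agent(simulate.PRESETS["WT"].params, ld186_5d, seed=3)
        cls = classify_ld(s, window_days=5)
        assert cls.call == "rhythmic_LD"
        assert cls.peak_times_zt[0] == pytest.approx(9.0, abs=1.5)

    def test_constant_rate_agent_arrhythmic(self, ld186_5d):
        hits = 0
        for seed in range(100):
            s = simulate.simulate_agent(
                simulate.AgentParams(baseline_rate=3.0), ld186_5d, seed=seed
            )
            hits += classify_ld(s, window_days=5).call == "arrhythmic_LD"
        assert hits >= 90

    def test_bimodal_agent_arrhythmic(self, ld186_5d):
        zt = np.tile(np.arange(288) / 12.0, 5)
        lam = 2.0 + 6.0 * (
            np.exp(3.0 * (np.cos(2 * np.pi * (zt - 5) / 24) - 1))
            + np.exp(3.0 * (np.cos(2 * np.pi * (zt - 13) / 24) - 1))
        )
        counts = np.random.default_rng(0).poisson(lam)
        cls = classify_ld(_series(counts, ld186_5d), window_days=5)
        assert cls.call == "arrhythmic_LD"
        assert cls.per_day_peak_count[0] == 2

    def test_inactive_animal_flagged(self, ld186_5d):
        cls = classify_ld(_series(np.zeros(5 * 288), ld186_5d), window_days=5)
        assert cls.call == "inactive"

    def test_scale_invariance(self, ld186_5d):
        s = simulate.simulate_agent(simulate.PRESETS["WT"].params, ld186_5d, seed=11)
        a = classify_ld(s, window_days=5)
        s10 = _series(s.counts * 10.0, ld186_5d)
        b = classify_ld(s10, window_days=5)
        assert a.call == b.call and a.per_day_peak_count == b.per_day_peak_count


class TestGroupProfile:
    def test_single_animal_equals_its_profile(self, ld186_5d, rng):
        s = _series(rng.poisson(3.0, 5 * 288), ld186_5d)
        grid, mean, sem, n = group_daily_profile([s], window_days=5)
        np.testing.assert_allclose(mean, average_day(s, 5).raw_mean)
        assert n == 1 and (sem == 0).all()

    def test_identical_animals_zero_sem(self, ld186_5d):
        s1 = _series(np.tile(np.arange(288.0), 5), ld186_5d)
        s2 = _series(np.tile(np.arange(288.0), 5), ld186_5d)
        _, mean, sem, _ = group_daily_profile([s1, s2], window_days=5)
        assert (sem == 0).all()

    def test_wt_cohort_single_midday_maximum(self, ld186_5d):
        cohort = simulate.simulate_cohort("WT", 32, ld186_5d, seed=21)
        grid, mean, _, n = group_daily_profile(cohort, window_days=5, only_rhythmic=True)
        assert n >= 29
        assert 7.0 <= grid[int(np.argmax(circular_smooth(mean, 4)))] <= 11.0

    def test_empty_group_rejected(self, ld186_5d):
        s = _series(np.zeros(5 * 288), ld186_5d)
        with pytest.raises(ValueError):
            group_daily_profile([s], window_days=5, only_rhythmic=True)


class TestOnsetOffset:
    def test_triangular_profile_symmetric_crossings(self):
        zt = np.arange(288) / 12.0
        tri = 10.0 - np.abs(zt - 12.0) * (10.0 / 12.0)  # peak ZT12, min ZT0
        prof = AverageDayProfile(np.arange(288) * 5.0, tri, tri, 1, 0.0)
        oo = onset_offset(prof)
        assert oo.onset_zt == pytest.approx(6.0, abs=1e-9)
        assert oo.offset_zt == pytest.approx(18.0, abs=1e-9)

    def test_square_profile_crossings_at_step_edges(self):
        vals = np.where((np.arange(288) >= 48) & (np.arange(288) < 144), 10.0, 2.0)
        prof = AverageDayProfile(np.arange(288) * 5.0, vals, vals.astype(float), 1, 0.0)
        oo = onset_offset(prof)
        # median equals the low level; crossings sit at the step edges to
        # within one bin under the piecewise-linear convention
        assert oo.onset_zt == pytest.approx(4.0, abs=5.0 / 60.0 + 1e-9)
        assert oo.offset_zt == pytest.approx(12.0, abs=5.0 / 60.0 + 1e-9)

    def test_constant_profile_rejected(self):
        prof = _profile(np.full(288, 3.0))
        with pytest.raises(ValueError, match="no phase"):
            onset_offset(prof)

    def test_circular_shift_equivariance(self, rng):
        base = rng.poisson(5.0, 288) + 20.0 * np.exp(
            3.0 * (np.cos(2 * np.pi * (np.arange(288) / 12.0 - 9) / 24) - 1)
        )
        p0 = _profile(base)
        oo0 = onset_offset(p0)
        for shift_bins in (12, 60, 171):
            oo = onset_offset(_profile(np.roll(base, shift_bins)))
            d = shift_bins * 5.0 / 60.0
            assert (oo.onset_zt - oo0.onset_zt) % 24.0 == pytest.approx(d, abs=1e-9)
            assert (oo.offset_zt - oo0.offset_zt) % 24.0 == pytest.approx(d, abs=1e-9)


class TestPartitionAndPulses:
    def test_dark_only_agent_has_zero_light_mean(self, ld186_5d):
        mask = ActivitySeries("a", np.zeros(5 * 288), 5, ld186_5d).light_mask()
        counts = np.where(mask, 0.0, 5.0)
        part = light_dark_partition(_series(counts, ld186_5d))
        assert part["mean_L"] == 0.0 and part["mean_D"] == 5.0

    def test_constant_conditions_grand_mean(self, dd_12d):
        s = simulate.simulate_agent(simulate.AgentParams(baseline_rate=4.0), dd_12d, seed=2)
        part = light_dark_partition(s)
        assert part["condition"] == "DD"
        assert part["mean"] == pytest.approx(4.0, abs=0.1)

    def test_short_ld_series_rejected(self):
        sched = make_schedule("LD18:6", span_days=2)
        with pytest.raises(ValueError):
            light_dark_partition(_series(np.ones(2 * 288), sched))

    def test_zero_masking_agent_pulse_delta_near_zero(self):
        base = make_schedule("LD18:6", span_days=5)
        sched = LightSchedule(
            base.segments, base.label, base.photoperiod_h, [Pulse(2 * 24 + 8.0, 2.0, False)]
        )
        deltas = []
        for seed in range(30):
            s = simulate.simulate_agent(
                simulate.AgentParams(baseline_rate=3.0), sched, seed=seed
            )
            deltas.append(pulse_response(s).delta)
        se = np.std(deltas, ddof=1) / np.sqrt(len(deltas))
        assert abs(np.mean(deltas)) < 3 * se

    def test_pdf_null_pulse_directions(self):
        base = make_schedule("LD18:6", span_days=5)
        dark = LightSchedule(
            base.segments, base.label, base.photoperiod_h, [Pulse(2 * 24 + 8.0, 2.0, False)]
        )
        light = LightSchedule(
            base.segments, base.label, base.photoperiod_h, [Pulse(2 * 24 + 20.0, 2.0, True)]
        )
        p = simulate.PRESETS["pdf-null"].params
        d_pos = sum(
            pulse_response(simulate.simulate_agent(p, dark, seed=s)).delta > 0
            for s in range(20)
        )
        l_neg = sum(
            pulse_response(simulate.simulate_agent(p, light, seed=s)).delta < 0
            for s in range(20)
        )
        assert d_pos >= 19 and l_neg >= 19

    def test_missing_pulse_rejected(self, ld186_5d):
        with pytest.raises(ValueError, match="no pulses"):
            pulse_response(_series(np.ones(5 * 288), ld186_5d))
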