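"""Light schedules, ZT bookkeeping and monitor-file round trips."""

from datetime import datetime

import numpy as np
import pandas as pd
import pytest

from chronobug.schedules import (
    ActivitySeries,
    MonitorTable,
    Pulse,
    concat_schedules,
    make_schedule,
    monitor_to_series,
    read_monitor,
    write_monitor,
    zt_of,
)


class TestMakeSchedule:
    def test_ld186_five_days_alternates_on_off(self):
        s = make_schedule("LD18:6", span_days=5)
        assert len(s.segments) == 10
        assert [seg.light_on for seg in s.segments] == [True, False] * 5
        assert all(seg.duration_h == 18.0 for seg in s.segments[::2])
        assert all(seg.duration_h == 6.0 for seg in s.segments[1::2])

    def test_dd_single_dark_segment(self):
        s = make_schedule("DD", span_days=12)
        assert len(s.segments) == 1
        assert s.segments[0].duration_h == 288.0
        assert not s.segments[0].light_on

    def test_dark_pulse_overrides_photophase(self):
        s = make_schedule("LD18:6", pulses=[(8.0, 2.0, False)], span_days=5)
        assert s.light_at(8.5) is False
        assert bool(s.light_at(7.9)) is True
        assert bool(s.light_at(10.1)) is True

    def test_segment_durations_sum_to_span(self):
        for label, days in [("LD18:6", 5), ("LD12:12", 10), ("LL", 3)]:
            s = make_schedule(label, span_days=days)
            assert sum(seg.duration_h for seg in s.segments) == pytest.approx(24.0 * days)

    def test_pulse_outside_span_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            make_schedule("LD18:6", pulses=[(130.0, 2.0, False)], span_days=5)

    def test_mismatched_ld_label_rejected(self):
        with pytest.raises(ValueError):
            make_schedule("LD18:7")


class TestZeitgeberTime:
    def test_lights_on_maps_to_zero_and_offsets_follow(self):
        sched = make_schedule("LD18:6", span_days=5)
        t0 = datetime(2024, 3, 1, 6, 0)
        assert zt_of(datetime(2024, 3, 1, 6, 0), sched, t0) == 0.0
        assert zt_of(datetime(2024, 3, 1, 14, 0), sched, t0) == 8.0

    def test_lights_off_of_ld1212_is_zt12(self):
        sched = make_schedule("LD12:12", span_days=5)
        t0 = datetime(2024, 3, 1, 6, 0)
        assert zt_of(datetime(2024, 3, 2, 18, 0), sched, t0) == 12.0

    def test_periodic_with_24h(self):
        sched = make_schedule("LD18:6", span_days=5)
        t0 = datetime(2024, 3, 1, 6, 0)
        for hour in (0, 5, 13, 23):
            a = zt_of(datetime(2024, 3, 1, 6 + hour % 18, hour % 60), sched, t0)
            b = zt_of(datetime(2024, 3, 2, 6 + hour % 18, hour % 60), sched, t0)
            assert a == pytest.approx(b)

    def test_outside_span_rejected(self):
        sched = make_schedule("LD18:6", span_days=5)
        t0 = datetime(2024, 3, 1, 6, 0)
        with pytest.raises(ValueError):
            zt_of(datetime(2024, 3, 10, 6, 0), sched, t0)

    def test_constant_condition_continues_ld_phase(self):
        sched = concat_schedules(
            make_schedule("LD18:6", span_days=5), make_schedule("DD", span_days=12)
        )
        # 8 h into the first DD day is still ZT8
        assert sched.zt(5 * 24.0 + 8.0) == pytest.approx(8.0)


class TestMonitorIO:
    def _table(self, counts, bin_minutes=5):
        counts = np.asarray(counts)
        ts = pd.date_range("2024-03-01 06:00", periods=len(counts), freq=f"{bin_minutes}min")
        return MonitorTable("m1", ts, counts, bin_minutes)

    def test_small_fixture_shape(self, tmp_path):
        tbl = self._table([[0, 1], [2, 0], [5, 3]])
        p = tmp_path / "m.txt"
        write_monitor(tbl, p)
        back = read_monitor(p, 5)
        assert back.counts.shape == (3, 2)
        np.testing.assert_array_equal(back.counts, [[0, 1], [2, 0], [5, 3]])

    def test_round_trip_bit_exact(self, tmp_path, rng):
        tbl = self._table(rng.poisson(3, size=(288, 4)))
        p = tmp_path / "m.txt"
        write_monitor(tbl, p)
        back = read_monitor(p, 5)
        np.testing.assert_array_equal(back.counts, tbl.counts)
        assert (back.timestamps == tbl.timestamps).all()

    def test_full_day_at_5min_is_288_rows(self, tmp_path, rng):
        tbl = self._table(rng.poisson(2, size=(288, 1)))
        p = tmp_path / "m.txt"
        write_monitor(tbl, p)
        assert len(read_monitor(p, 5).timestamps) == 288

    def test_gap_names_offending_row(self):
        ts = pd.DatetimeIndex(
            ["2024-03-01 06:00", "2024-03-01 06:05", "2024-03-01 06:15"]
        )
        with pytest.raises(ValueError, match="row 1"):
            MonitorTable("m", ts, np.zeros((3, 1), dtype=int), 5)

    def test_negative_counts_hard_error(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("1\t1-MAR-24\t06:00:00\t1\t-3\n")
        with pytest.raises(ValueError, match="negative"):
            read_monitor(p, 5)

    def test_error_status_rows_flagged_missing(self, tmp_path):
        p = tmp_path / "m.txt"
        p.write_text(
            "1\t1-MAR-24\t06:00:00\t1\t4\n"
            "2\t1-MAR-24\t06:05:00\t51\t0\n"
            "3\t1-MAR-24\t06:10:00\t1\t2\n"
        )
        tbl = read_monitor(p, 5)
        np.testing.assert_array_equal(tbl.missing, [False, True, False])

    def test_monitor_to_series_binds_schedule(self, tmp_path, rng):
        tbl = self._table(rng.poisson(3, size=(288, 2)))
        sched = make_schedule("LD18:6", span_days=1)
        series = monitor_to_series(tbl, sched, tbl.timestamps[0].to_pydatetime())
        assert len(series) == 2
        assert series[0].t0_zt == 0.0
        assert series[0].light_mask()[:12].all()


class TestActivitySeries:
    def test_light_mask_follows_schedule(self):
        sched = make_schedule("LD18:6", span_days=2)
        s = ActivitySeries("a", np.zeros(2 * 288), 5, sched)
        m = s.light_mask()
        assert m[: 18 * 12].all() and not m[18 * 12 : 24 * 12].any()

    def test_slice_preserves_alignment(self):
        sched = make_schedule("LD18:6", span_days=3)
        s = ActivitySeries("a", np.arange(3 * 288, dtype=float), 5, sched)
        part = s.slice_hours(24.0, 48.0)
        assert part.t0_zt == 0.0
        assert part.counts[0] == 288.0

    def test_series_longer_than_schedule_rejected(self):
        sched = make_schedule("LD18:6", span_days=1)
        with pytest.raises(ValueError):
            ActivitySeries("a", np.zeros(2 * 288), 5, sched)
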