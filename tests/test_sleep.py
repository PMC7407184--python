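"""Sleep detector: smoothing, quiescence, light moderation, interval algebra."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from somnipy import (
    DetectorConfig,
    RecordError,
    SleepInterval,
    analyze_sleep,
    apply_light_moderator,
    classify_depth,
    detect_quiescence,
    drop_shallow,
    merge_intervals,
    moving_average,
)

from _oracles import brute_moving_average, brute_sleep_intervals
from conftest import make_record

T0 = pd.Timestamp("2020-07-06T12:00:00")


def iv(start_min, end_min):
    return (T0 + pd.Timedelta(minutes=start_min),
            T0 + pd.Timedelta(minutes=end_min))


class TestMovingAverage:
    @pytest.mark.parametrize("series,window,expected", [
        ([5, 5, 5, 5], 3, [5, 5, 5, 5]),
        ([0, 3, 6], 3, [1.5, 3, 4.5]),
        ([1, 2, 3, 4], 1, [1, 2, 3, 4]),
    ])
    def test_examples(self, series, window, expected):
        np.testing.assert_allclose(moving_average(series, window), expected)

    @given(st.lists(st.floats(0, 1e6), min_size=1, max_size=60),
           st.sampled_from([1, 3, 5, 7, 9]))
    def test_matches_brute_force_and_stays_in_range(self, series, window):
        if window > len(series):
            window = 1
        got = moving_average(series, window)
        np.testing.assert_allclose(got, brute_moving_average(series, window),
                                   rtol=1e-12, atol=1e-9)
        assert got.min() >= min(series) - 1e-9
        assert got.max() <= max(series) + 1e-9

    def test_rejects_even_or_oversized_window(self):
        with pytest.raises(ValueError):
            moving_average([1, 2, 3], 2)
        with pytest.raises(ValueError):
            moving_average([1, 2, 3], 5)


class TestDetectQuiescence:
    def test_all_quiet_is_one_interval_spanning_segment(self):
        rec = make_record(n=960)  # 8 h of zero motion
        out = detect_quiescence(rec.timestamps, rec.channel("motion"),
                                1.0, 30.0)
        assert out == [(rec.start, rec.end)]

    def test_no_quiet_epochs_empty(self):
        rec = make_record(n=100, motion=np.full(100, 50.0))
        assert detect_quiescence(rec.timestamps, rec.channel("motion"),
                                 1.0, 30.0) == []

    def test_runs_never_bridge_segment_breaks(self):
        idx = list(T0 + pd.to_timedelta(np.arange(10) * 30, unit="s"))
        idx += list(idx[-1] + pd.Timedelta(minutes=20)
                    + pd.to_timedelta(np.arange(10) * 30, unit="s"))
        times = pd.DatetimeIndex(idx)
        segs = [(times[0], times[9] + pd.Timedelta(seconds=30)),
                (times[10], times[19] + pd.Timedelta(seconds=30))]
        out = detect_quiescence(times, np.zeros(20), 1.0, 30.0, segments=segs)
        assert len(out) == 2
        assert out[0][1] == segs[0][1]
        assert out[1][0] == segs[1][0]


class TestLightModerator:
    def cfg(self, mode, thr=10.0):
        return DetectorConfig(light_mode=mode, light_threshold=thr)

    def test_off_and_all_dark_leave_intervals_unchanged(self):
        rec = make_record(n=240, light=np.ones(240))
        ivs = [iv(0, 60), iv(90, 120)]
        for mode in ("off", "gate", "veto"):
            out = apply_light_moderator(ivs, rec.timestamps,
                                        rec.channel("light"), self.cfg(mode))
            assert out == ivs

    def test_gate_advances_start_past_bright_first_hour(self):
        light = np.concatenate([np.full(120, 300.0), np.full(360, 1.0)])
        rec = make_record(n=480, light=light)
        out = apply_light_moderator([iv(0, 240)], rec.timestamps,
                                    rec.channel("light"), self.cfg("gate"))
        assert out == [iv(60, 240)]  # first dark epoch is at minute 60

    def test_veto_discards_bright_interval_whole(self):
        # first 2 h dark, rest brightly lit
        light = np.full(480, 300.0)
        light[:240] = 1.0
        rec = make_record(n=480, light=light)
        cfg = self.cfg("veto")
        out = apply_light_moderator([iv(0, 120), iv(130, 230)],
                                    rec.timestamps, rec.channel("light"), cfg)
        # the dark interval survives; the daytime bright one is removed whole
        assert out == [iv(0, 120)]

    def test_missing_light_rejected_unless_off(self):
        with pytest.raises(RecordError):
            apply_light_moderator([iv(0, 10)], pd.DatetimeIndex([T0]),
                                  None, self.cfg("veto"))


class TestIntervalAlgebra:
    def test_merge_examples(self):
        assert merge_intervals([iv(0, 30), iv(50, 80)], 10) == \
            [iv(0, 30), iv(50, 80)]
        assert merge_intervals([iv(0, 30), iv(35, 60), iv(65, 90)], 10) == \
            [iv(0, 90)]
        assert merge_intervals([iv(0, 30)], 10) == [iv(0, 30)]

    def test_merge_rejects_overlap(self):
        with pytest.raises(ValueError):
            merge_intervals([iv(0, 30), iv(20, 50)], 10)

    @given(st.lists(st.tuples(st.integers(0, 2000), st.integers(1, 120)),
                    min_size=0, max_size=20),
           st.integers(0, 30))
    def test_merge_and_drop_idempotent(self, raw, gap):
        ivs, cursor = [], 0
        for off, dur in raw:
            start = cursor + off
            ivs.append(iv(start, start + dur))
            cursor = start + dur + 1
        merged = merge_intervals(ivs, gap)
        assert merge_intervals(merged, gap) == merged
        kept = drop_shallow(merged, 30)
        assert drop_shallow(kept, 30) == kept

    @pytest.mark.parametrize("minutes,kept", [(25, False), (29, False),
                                              (30, True), (31, True),
                                              (175, True)])
    def test_drop_shallow_strict_boundary(self, minutes, kept):
        out = drop_shallow([iv(0, minutes)], 30)
        assert (len(out) == 1) == kept

    @pytest.mark.parametrize("minutes,depth", [(179, "sleep"), (180, "sleep"),
                                               (181, "deep"), (462, "deep")])
    def test_classify_depth_strict_boundary(self, minutes, depth):
        out = classify_depth([iv(0, minutes)], 180)
        assert out[0].depth == depth

    def test_interval_duration_contract(self):
        span = SleepInterval(start=pd.Timestamp("2020-07-06T13:00:00"),
                             end=pd.Timestamp("2020-07-06T15:55:00"))
        assert span.duration == 175.0


class TestAnalyzeSleep:
    def test_degenerate_all_quiet_day_is_one_deep_interval(self):
        rec = make_record(n=2880)  # 24 h, zero motion, zero light
        cfg = DetectorConfig(motion_threshold=1.0, light_threshold=1.0)
        rep = analyze_sleep(rec, cfg)
        assert len(rep.windows) == 1
        _, ivs, total = rep.windows[0]
        assert len(ivs) == 1
        assert ivs[0].depth == "deep"
        assert total == 24 * 60

    def test_missing_motion_channel_rejected(self):
        rec = make_record(n=100)
        rec.data["motion"] = np.nan
        with pytest.raises(RecordError, match="motion"):
            analyze_sleep(rec)

    def test_interval_crossing_noon_credited_to_midpoint_window(self):
        # 2-day record; quiet block Tue 10:00-14:10 crosses the Tue noon
        # boundary with its midpoint just after noon
        n = 2 * 2880
        motion = np.full(n, 50.0)
        motion[2640:3140] = 0.0
        rec = make_record(n=n, motion=motion)
        cfg = DetectorConfig(motion_threshold=1.0, light_mode="off")
        rep = analyze_sleep(rec, cfg)
        totals = rep.nightly_minutes
        assert len(totals) == 2
        # midpoint 12:00 falls in the second window [noon day2, end)
        assert totals[0] == 0
        assert totals[1] > 0

    def test_raising_motion_threshold_never_decreases_sleep(self):
        rng = np.random.default_rng(5)
        rec = make_record(n=2880, motion=rng.gamma(2, 10, 2880))
        prev = -1.0
        for thr in [1, 5, 10, 20, 40, 80]:
            cfg = DetectorConfig(motion_threshold=float(thr),
                                 light_mode="off")
            total = sum(analyze_sleep(rec, cfg).nightly_minutes)
            assert total >= prev
            prev = total

    def test_matches_brute_force_on_random_records(self):
        rng = np.random.default_rng(11)
        for _ in range(30):
            n = int(rng.integers(20, 200))
            # block-structured motion so runs of every length appear
            motion = np.abs(np.repeat(rng.gamma(1.0, 30.0, 1 + n // 8),
                                      8)[:n] + rng.normal(0, 1, n))
            ma = int(rng.choice([1, 3, 5]))
            thr = float(rng.uniform(1, 40))
            gap = float(rng.choice([0, 5, 10, 30]))
            rec = make_record(n=n, motion=motion)
            cfg = DetectorConfig(ma_window=ma, motion_threshold=thr,
                                 light_mode="off", merge_gap=gap,
                                 min_duration=30)
            rep = analyze_sleep(rec, cfg)
            got = sorted(
                [(v.start, v.end, v.depth) for _, ivs, _ in rep.windows
                 for v in ivs])
            expected = brute_sleep_intervals(
                rec.timestamps, motion, 30.0, ma_window=ma,
                motion_threshold=thr, merge_gap_min=gap,
                min_duration_min=30, deep_duration_min=180)
            assert got == expected

    def test_week_recovery_within_tolerance(self, default_week):
        record, truth = default_week
        rep = analyze_sleep(record)
        detected = [v for _, ivs, _ in rep.windows for v in ivs]
        tol_min = 2 * 0.5 + rep.config.merge_gap  # 2 epochs + merge gap
        for s, e in truth.spans("sleep"):
            true_dur = (e - s) / pd.Timedelta(minutes=1)
            overlapping = [v for v in detected
                           if v.start < e and v.end > s]
            assert len(overlapping) == 1
            assert abs(overlapping[0].duration - true_dur) <= tol_min
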