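import numpy as np
import pytest

from flybeam import (
    BinnedSeries,
    LightSchedule,
    average_day,
    bin_activity,
    bin_crossings,
    compare_hourly,
    compare_totals,
    day_night_totals,
    frame_distances,
    group_mean,
    group_median,
    sleep_binned,
    sleep_bouts,
    virtual_dam,
)
from flybeam.activity import CrossingEvents
from flybeam.errors import (
    GridAlignmentError,
    InsufficientDaysError,
    StatisticUndefinedError,
)

from conftest import make_cleaned


class TestFrameDistances:
    def test_stationary_fly(self, loco_geom):
        c = make_cleaned(np.arange(100), np.full(100, 10.0), np.full(100, 10.0), loco_geom)
        d = frame_distances(c)
        assert len(d) == 99 and d.sum() == 0.0

    def test_three_four_five(self, loco_geom):
        c = make_cleaned([0, 1], [0.0, 3.0], [0.0, 4.0], loco_geom)
        assert frame_distances(c).tolist() == [5.0]

    def test_random_walk_matches_hypotenuse_sum(self, rng, loco_geom):
        n = 1000
        x = np.cumsum(rng.normal(0, 1, n)) % 100
        y = np.cumsum(rng.normal(0, 1, n)) % 100
        c = make_cleaned(np.arange(n), x, y, loco_geom)
        expected = sum(
            np.sqrt((x[i + 1] - x[i]) ** 2 + (y[i + 1] - y[i]) ** 2) for i in range(n - 1)
        )
        assert frame_distances(c).sum() == pytest.approx(expected, rel=1e-12)

    def test_single_frame_empty(self, loco_geom):
        c = make_cleaned([0], [1.0], [1.0], loco_geom)
        assert len(frame_distances(c)) == 0


class TestBinActivity:
    def test_constant_speed(self):
        # 1 px/frame at 5 fps: 3000 px per complete 10-min bin
        n = 5 * 60 * 25  # 25 minutes
        d = np.ones(n - 1)
        b = bin_activity(d, np.arange(n), fps=5.0, bin_minutes=10)
        assert len(b) == 2  # trailing incomplete bin dropped
        assert b.values.tolist() == [3000.0, 3000.0]

    @pytest.mark.parametrize("bin_minutes", [1, 10, 30, 60])
    def test_conservation_over_complete_bins(self, rng, bin_minutes):
        n = 5 * 3600 * 2  # two hours at 5 fps
        d = rng.exponential(1.0, n - 1)
        b = bin_activity(d, np.arange(n), fps=5.0, bin_minutes=bin_minutes)
        covered = len(b) * bin_minutes * 60 * 5  # frames inside complete bins
        assert b.values.sum() == pytest.approx(d[: covered - 1].sum(), rel=1e-12)

    def test_matches_brute_force_assignment(self, rng):
        n = 4000
        frames = np.sort(rng.choice(20_000, n, replace=False))
        d = rng.exponential(1.0, n - 1)
        b = bin_activity(d, frames, fps=5.0, bin_minutes=30, duration_s=4000.0)
        expected = np.zeros(len(b))
        for i in range(n - 1):
            t = frames[i] / 5.0
            k = int(t // (30 * 60))
            if k < len(expected):
                expected[k] += d[i]
        np.testing.assert_allclose(b.values, expected, rtol=1e-12)


class TestGroupStats:
    def grid(self, values, n=4):
        return BinnedSeries(10, np.arange(n) * 600.0, values)

    def test_single_fly_identity(self):
        b = self.grid([1.0, 2.0, 3.0, 4.0])
        assert group_mean([b]).values.tolist() == [1, 2, 3, 4]

    def test_two_fly_mean_median(self):
        a, b = self.grid([0.0] * 4), self.grid([10.0] * 4)
        assert group_mean([a, b]).values.tolist() == [5.0] * 4
        assert group_median([a, b]).values.tolist() == [5.0] * 4

    def test_sixteen_flies_match_oracle(self, rng):
        mats = rng.uniform(0, 10, size=(16, 24))
        group = [self.grid(m, n=24) for m in mats]
        np.testing.assert_allclose(group_mean(group).values, mats.mean(axis=0))
        np.testing.assert_allclose(group_median(group).values, np.median(mats, axis=0))

    def test_mismatched_grids_rejected(self):
        a = BinnedSeries(10, np.arange(4) * 600.0, np.zeros(4))
        b = BinnedSeries(30, np.arange(4) * 1800.0, np.zeros(4))
        with pytest.raises(GridAlignmentError):
            group_mean([a, b])


class TestVirtualBeam:
    def make(self, ys, geom):
        n = len(ys)
        x = np.full(n, 25.0)
        return make_cleaned(np.arange(n), x, ys, geom)

    @pytest.fixture
    def geom(self):
        from flybeam import ChamberGeometry
        return ChamberGeometry(x_min=0, y_min=0, x_max=50, y_max=230, midline=115.0)

    def test_single_crossing(self, geom):
        ev = virtual_dam(self.make([50.0, 200.0], geom))
        assert len(ev) == 1 and ev.frames.tolist() == [1]

    def test_alternating_sides(self, geom):
        ys = [50.0, 200.0] * 5
        ev = virtual_dam(self.make(ys, geom))
        assert len(ev) == 9

    def test_exact_midline_grazing_not_counted(self, geom):
        # fly touches the beam and retreats: held side never changes
        ev = virtual_dam(self.make([50.0, 115.0, 50.0], geom))
        assert len(ev) == 0

    def test_crossing_through_midline_counted_once(self, geom):
        ev = virtual_dam(self.make([50.0, 115.0, 200.0], geom))
        assert len(ev) == 1

    def test_matches_brute_force_sign_change(self, rng, geom):
        n = 5000
        ys = np.clip(np.cumsum(rng.normal(0, 8, n)) + 115.0, 0.0, 229.9)
        ev = virtual_dam(self.make(ys, geom))
        # brute-force: track held side with the same tie rule
        side, count = None, 0
        for yi in ys:
            s = -1 if yi < 115 else (+1 if yi > 115 else (side if side is not None else -1))
            if side is not None and s != side:
                count += 1
            side = s
        assert len(ev) == count
        assert len(ev) <= n - 1

    def test_reflection_symmetry(self, rng, geom):
        n = 2000
        ys = np.clip(np.cumsum(rng.normal(0, 5, n)) + 115.0, 0.0, 229.9)
        ev = virtual_dam(self.make(ys, geom))
        reflected = np.clip(230.0 - ys, 0.0, 229.9)
        ev_r = virtual_dam(self.make(reflected, geom))
        assert len(ev) == len(ev_r)

    def test_scale_invariance(self, rng):
        from flybeam import ChamberGeometry
        n = 2000
        ys = np.clip(np.cumsum(np.random.default_rng(3).normal(0, 5, n)) + 115.0, 0.0, 229.9)
        g1 = ChamberGeometry(x_min=0, y_min=0, x_max=50, y_max=230, midline=115.0)
        g2 = ChamberGeometry(x_min=0, y_min=0, x_max=150, y_max=690, midline=345.0)
        ev1 = virtual_dam(self.make(ys, g1))
        c2 = make_cleaned(np.arange(n), np.full(n, 75.0), ys * 3.0, g2)
        ev2 = virtual_dam(c2)
        assert len(ev1) == len(ev2)
        # distances scale by the same factor
        d1 = frame_distances(self.make(ys, g1)).sum()
        assert frame_distances(c2).sum() == pytest.approx(3.0 * d1, rel=1e-9)

    def test_interpolated_run_no_internal_crossings(self, geom):
        # constant-position runs (the cleaner's output) cross at most at the edges
        ys = [50.0, 115.0, 115.0, 115.0, 200.0]
        ev = virtual_dam(self.make(ys, geom))
        assert len(ev) == 1


class TestBinCrossings:
    def test_no_events_all_zero(self):
        ev = CrossingEvents(np.array([], dtype=np.int64), fps=5.0, n_frames=5 * 3600)
        b = bin_crossings(ev, 10)
        assert len(b) == 6 and not b.values.any()

    def test_one_event_per_minute(self):
        frames = np.arange(60) * 300  # one crossing per minute at 5 fps
        ev = CrossingEvents(frames, fps=5.0, n_frames=5 * 3600)
        b = bin_crossings(ev, 10)
        assert b.values.tolist() == [10.0] * 6

    def test_matches_histogram_oracle(self, rng):
        n_frames = 5 * 7200
        frames = np.sort(rng.choice(n_frames - 1, 500, replace=False)) + 1
        ev = CrossingEvents(frames, fps=5.0, n_frames=n_frames)
        b = bin_crossings(ev, 30)
        expected, _ = np.histogram(frames / 5.0, bins=len(b),
                                   range=(0, len(b) * 1800.0))
        np.testing.assert_array_equal(b.values, expected)


class TestSleep:
    def span_events(self, times, span):
        frames = (np.asarray(times, float) * 5).astype(np.int64)
        return CrossingEvents(frames, fps=5.0, n_frames=int(span * 5))

    def test_six_minute_gap_is_one_bout(self):
        ev = self.span_events([0, 360], span=360)
        bouts = sleep_bouts(ev, span=(0.0, 360.0))
        assert len(bouts) == 1
        assert bouts[0].duration_s == 360.0

    def test_four_minute_gaps_no_bouts(self):
        times = np.arange(0, 3601, 240)
        ev = self.span_events(times, span=3600)
        assert sleep_bouts(ev, span=(0.0, 3600.0)) == []

    def test_edges_count_as_quiescence(self):
        # no crossing in the first 10 minutes of the recording -> leading bout
        ev = self.span_events([600, 660], span=900)
        bouts = sleep_bouts(ev, span=(0.0, 900.0))
        assert bouts[0].start_s == 0.0 and bouts[0].end_s == 600.0

    def test_matches_brute_force_gap_scan(self, rng):
        span = 6 * 3600.0
        times = np.sort(rng.uniform(0, span, 60))
        ev = self.span_events(times, span=span)
        bouts = sleep_bouts(ev, span=(0.0, span))
        edges = np.concatenate([[0.0], ev.times, [span]])
        expected = [(a, b) for a, b in zip(edges[:-1], edges[1:]) if b - a >= 300.0]
        assert [(b.start_s, b.end_s) for b in bouts] == expected

    def test_sleep_minutes_never_exceed_bin_width(self, rng):
        span = 4 * 3600.0
        times = np.sort(rng.uniform(0, span, 20))
        ev = self.span_events(times, span=span)
        binned = sleep_binned(sleep_bouts(ev, span=(0.0, span)), 30, (0.0, span))
        assert (binned.values <= 30.0 + 1e-9).all()
        assert (binned.values >= 0).all()


class TestAverageDay:
    def daily(self, day_values, n_days, bin_minutes=60):
        vals = np.tile(day_values, n_days)
        starts = np.arange(len(vals)) * bin_minutes * 60.0
        return BinnedSeries(bin_minutes, starts, vals)

    def test_identical_days_equal_single_day(self):
        day = np.arange(24.0)
        b = self.daily(day, 3)
        prof = average_day(b, LightSchedule.ld(3), n_full_days=3)
        np.testing.assert_array_equal(prof.values, day)

    def test_two_contrasting_days_averaged(self):
        b = self.daily(np.zeros(24), 1)
        b2 = BinnedSeries(60, np.arange(48) * 3600.0,
                          np.concatenate([np.zeros(24), np.full(24, 10.0)]))
        prof = average_day(b2, LightSchedule.ld(2), n_full_days=2)
        assert prof.values.tolist() == [5.0] * 24

    def test_insufficient_days_raises(self):
        b = self.daily(np.arange(24.0), 1)
        with pytest.raises(InsufficientDaysError):
            average_day(b, LightSchedule.ld(2), n_full_days=2)


class TestDayNightTotals:
    def test_totals_split_by_phase(self):
        sched = LightSchedule.ld(1)
        vals = np.concatenate([np.full(72, 1.0), np.full(72, 3.0)])  # 10-min bins
        b = BinnedSeries(10, np.arange(144) * 600.0, vals)
        tot = day_night_totals(b, sched)
        assert tot["day"] == 72.0
        assert tot["night"] == 216.0

    def test_partial_phase_excluded(self):
        sched = LightSchedule.ld(1)
        b = BinnedSeries(10, np.arange(100) * 600.0, np.ones(100))  # < 24 h of data
        tot = day_night_totals(b, sched)
        assert tot["day"] == 72.0 and tot["night"] == 0.0


class TestCompareTotals:
    def test_welch_matches_closed_form(self):
        a, b = np.array([1.0, 2.0, 3.0]), np.array([2.0, 4.0, 6.0])
        t, p = compare_totals(a, b)
        # Welch formula by hand: t = (ma-mb)/sqrt(va/na + vb/nb)
        expected_t = (2.0 - 4.0) / np.sqrt(1.0 / 3 + 4.0 / 3)
        assert t == pytest.approx(expected_t, rel=1e-12)
        # Welch-Satterthwaite df = 50/17; p from the t distribution
        from scipy import stats as ss
        df = (1 / 3 + 4 / 3) ** 2 / ((1 / 3) ** 2 / 2 + (4 / 3) ** 2 / 2)
        assert p == pytest.approx(2 * ss.t.sf(abs(expected_t), df), rel=1e-9)

    def test_identical_groups_null(self, rng):
        a = rng.normal(0, 1, 16)
        t, p = compare_totals(a, a.copy())
        assert t == 0.0 and p == pytest.approx(1.0)

    def test_separated_groups_rejected_consistently(self, rng):
        rejections = 0
        for _ in range(200):
            a = rng.normal(0, 1, 16)
            b = rng.normal(5, 1, 16)
            _, p = compare_totals(a, b)
            rejections += p < 0.05
        assert rejections >= 198  # >= 99% power at a 5 SD shift

    def test_degenerate_groups_raise(self):
        with pytest.raises(StatisticUndefinedError):
            compare_totals([1.0], [2.0, 3.0])
        with pytest.raises(StatisticUndefinedError):
            compare_totals([1.0, 1.0], [1.0, 1.0])


class TestCompareHourly:
    def test_single_fly_never_a_discovery(self):
        res = compare_hourly(np.zeros((1, 24)), np.ones((1, 24)))
        assert not res.discovery.any()

    def test_all_tied_data_handled(self):
        res = compare_hourly(np.ones((4, 24)), np.ones((4, 24)))
        assert (res.pvalues == 1.0).all()
        assert not res.discovery.any()

    def test_injected_effect_discovered_with_direction(self, rng):
        a = rng.normal(0, 1, size=(16, 24))
        b = rng.normal(0, 1, size=(16, 24))
        b[:, 12:] += 3.0  # 3 SD shift in the night hours
        res = compare_hourly(a, b)
        assert res.discovery[12:].sum() >= 10
        assert all(res.higher_group[h] == "B" for h in range(12, 24) if res.discovery[h])


class TestDeadFlyFlag:
    def test_motionless_crossingless_fly_flagged(self, loco_geom):
        from flybeam import flag_dead_fly
        from conftest import make_cleaned
        n = 5 * 3600
        c = make_cleaned(np.arange(n), np.full(n, 10.0), np.full(n, 10.0), loco_geom)
        assert flag_dead_fly(c, window_s=3600.0)

    def test_active_fly_not_flagged(self, rng, loco_geom):
        from flybeam import flag_dead_fly
        from conftest import make_cleaned
        n = 5 * 3600
        y = np.clip(np.cumsum(rng.normal(0, 3, n)) + 115, 0, 229.9)
        c = make_cleaned(np.arange(n), np.full(n, 10.0), y, loco_geom)
        assert not flag_dead_fly(c, window_s=3600.0)
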