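import numpy as np
import pytest

from flybeam import (
    TrackingSeries,
    flag_out_of_bounds,
    infer_chamber_limits,
    interpolate_out_of_bounds,
)
from flybeam.cleaning import clean_series
from flybeam.errors import (
    DegenerateGeometryError,
    GeometryInferenceError,
    UnrecoverableSeriesError,
)

from conftest import random_series


def series_from(x, y, lik=None, fps=5.0):
    n = len(x)
    lik = np.ones(n) if lik is None else np.asarray(lik, float)
    return TrackingSeries(frames=np.arange(n), x=np.asarray(x, float),
                          y=np.asarray(y, float), likelihood=lik, fps=fps)


def brute_force_interpolate(x, y, mask):
    """Reference: linear scan for flanking unmasked indices, midpoint rule."""
    x, y = x.copy(), y.copy()
    n = len(x)
    good = [i for i in range(n) if not mask[i]]
    for i in range(n):
        if not mask[i]:
            continue
        prev = max((g for g in good if g < i), default=None)
        nxt = min((g for g in good if g > i), default=None)
        if prev is None:
            prev = nxt
        if nxt is None:
            nxt = prev
        x[i] = 0.5 * (x[prev] + x[nxt])
        y[i] = 0.5 * (y[prev] + y[nxt])
    return x, y


class TestInferChamberLimits:
    def test_recovers_uniform_rectangle(self, rng):
        x = rng.uniform(10, 110, 10_000)
        y = rng.uniform(20, 70, 10_000)
        g = infer_chamber_limits(series_from(x, y))
        assert abs(g.x_min - 10) <= 2 and abs(g.x_max - 110) <= 2
        assert abs(g.y_min - 20) <= 2 and abs(g.y_max - 70) <= 2

    def test_contaminated_series_still_recovered(self, rng):
        """1% low-likelihood misdetections plus rare confident strays 50 px out."""
        n = 10_000
        x = rng.uniform(10, 110, n)
        y = rng.uniform(20, 70, n)
        lik = rng.uniform(0.95, 1.0, n)
        bad = rng.random(n) < 0.01          # typical misdetections: low confidence
        x[bad] += 100.0
        lik[bad] = rng.uniform(0, 0.5, bad.sum())
        stray = rng.random(n) < 0.0005      # confident strays, rejected by quantiles
        x[stray] = 160.0
        g = infer_chamber_limits(series_from(x, y, lik))
        assert abs(g.x_min - 10) <= 3 and abs(g.x_max - 110) <= 3
        assert abs(g.y_min - 20) <= 3 and abs(g.y_max - 70) <= 3

    def test_single_point_degenerate(self):
        s = series_from(np.full(500, 42.0), np.full(500, 17.0))
        with pytest.raises(DegenerateGeometryError):
            infer_chamber_limits(s)

    def test_too_few_confident_detections(self, rng):
        s = series_from(rng.uniform(0, 100, 50), rng.uniform(0, 100, 50))
        with pytest.raises(GeometryInferenceError):
            infer_chamber_limits(s)

    def test_low_likelihood_points_ignored(self, rng):
        n = 5000
        x = rng.uniform(10, 110, n)
        y = rng.uniform(20, 70, n)
        lik = np.ones(n)
        bad = rng.random(n) < 0.05
        x[bad] = 500.0
        lik[bad] = 0.1
        g = infer_chamber_limits(series_from(x, y, lik))
        assert g.x_max < 130


class TestFlagOutOfBounds:
    def test_all_inside_all_confident(self, rng, loco_geom):
        s = random_series(rng, 100, loco_geom)
        assert not flag_out_of_bounds(s, loco_geom).any()

    def test_single_outside_point(self, loco_geom):
        s = series_from([10, -5, 20], [10, 10, 10])
        mask = flag_out_of_bounds(s, loco_geom)
        assert mask.tolist() == [False, True, False]

    def test_matches_per_frame_oracle(self, rng, loco_geom):
        n = 1000
        x = rng.uniform(-50, 200, n)
        y = rng.uniform(-50, 280, n)
        lik = rng.uniform(0, 1, n)
        x[rng.random(n) < 0.01] = np.nan
        s = series_from(x, y, lik)
        mask = flag_out_of_bounds(s, loco_geom, likelihood_floor=0.9)
        for i in range(n):
            expected = (
                not (np.isfinite(x[i]) and np.isfinite(y[i]))
                or not loco_geom.contains(x[i], y[i])
                or lik[i] < 0.9
            )
            assert mask[i] == expected


class TestInterpolate:
    def test_midpoint_of_flanking_detections(self, loco_geom):
        s = series_from([10, 999, 20], [10, 999, 20])
        mask = np.array([False, True, False])
        c = interpolate_out_of_bounds(s, mask, loco_geom)
        assert (c.x[1], c.y[1]) == (15.0, 15.0)

    def test_run_receives_shared_midpoint(self, loco_geom):
        s = series_from([0, -1, -1, -1, 10], [0, -1, -1, -1, 10])
        mask = np.array([False, True, True, True, False])
        c = interpolate_out_of_bounds(s, mask, loco_geom)
        assert c.x[1:4].tolist() == [5.0, 5.0, 5.0]
        assert c.y[1:4].tolist() == [5.0, 5.0, 5.0]

    def test_leading_run_copies_first_good(self, loco_geom):
        s = series_from([-1, -1, -1, 7, 8], [-1, -1, -1, 9, 9])
        mask = np.array([True, True, True, False, False])
        c = interpolate_out_of_bounds(s, mask, loco_geom)
        assert c.x[:3].tolist() == [7.0, 7.0, 7.0]
        assert c.y[:3].tolist() == [9.0, 9.0, 9.0]

    def test_trailing_run_copies_last_good(self, loco_geom):
        s = series_from([7, -1, -1], [9, -1, -1])
        mask = np.array([False, True, True])
        c = interpolate_out_of_bounds(s, mask, loco_geom)
        assert c.x.tolist() == [7.0, 7.0, 7.0]

    def test_all_masked_unrecoverable(self, loco_geom):
        s = series_from([-1, -2], [-1, -2])
        with pytest.raises(UnrecoverableSeriesError):
            interpolate_out_of_bounds(s, np.array([True, True]), loco_geom)

    def test_matches_brute_force_on_random_series(self, rng, loco_geom):
        for _ in range(30):
            n = int(rng.integers(5, 200))
            s = random_series(rng, n, loco_geom, oob_frac=0.1)
            mask = flag_out_of_bounds(s, loco_geom)
            if mask.all():
                continue
            c = interpolate_out_of_bounds(s, mask, loco_geom)
            ex, ey = brute_force_interpolate(s.x, s.y, mask)
            np.testing.assert_array_equal(c.x, ex)
            np.testing.assert_array_equal(c.y, ey)

    def test_linear_mode_time_weighted(self, loco_geom):
        s = series_from([0, -1, -1, -1, 8], [0, -1, -1, -1, 4])
        mask = np.array([False, True, True, True, False])
        c = interpolate_out_of_bounds(s, mask, loco_geom, mode="linear")
        assert c.x[1:4].tolist() == [2.0, 4.0, 6.0]
        assert c.y[1:4].tolist() == [1.0, 2.0, 3.0]


class TestCleaningInvariants:
    def test_post_cleaning_containment(self, rng, loco_geom):
        for _ in range(20):
            s = random_series(rng, 400, loco_geom, oob_frac=0.05)
            c, _ = clean_series(s, geometry=loco_geom)
            for xi, yi in zip(c.x, c.y):
                assert loco_geom.contains(xi, yi)

    def test_idempotence(self, rng, loco_geom):
        s = random_series(rng, 300, loco_geom, oob_frac=0.05)
        c1, _ = clean_series(s, geometry=loco_geom)
        s2 = TrackingSeries(frames=c1.frames, x=c1.x, y=c1.y,
                            likelihood=np.ones(len(c1)), fps=c1.fps)
        c2, rep = clean_series(s2, geometry=loco_geom)
        assert rep["n_flagged"] == 0
        np.testing.assert_array_equal(c1.x, c2.x)
        np.testing.assert_array_equal(c1.y, c2.y)

    def test_unmasked_positions_bit_identical(self, rng, loco_geom):
        s = random_series(rng, 500, loco_geom, oob_frac=0.1)
        mask = flag_out_of_bounds(s, loco_geom)
        c = interpolate_out_of_bounds(s, mask, loco_geom)
        np.testing.assert_array_equal(c.x[~mask], s.x[~mask])
        np.testing.assert_array_equal(c.y[~mask], s.y[~mask])
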