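import numpy as np
import pandas as pd
import pytest

import laketrack as lt
from laketrack.positioning import (
    filter_positions,
    flag_mortality,
    interpolate_gaps,
    distance_to_bottom,
    regularize,
)

from conftest import qpos_row


def fix(tag, t, x=np.nan, y=np.nan, depth=np.nan):
    return {
        "tag_id": tag,
        "timestamp": pd.Timestamp(t),
        "x": x,
        "y": y,
        "depth": depth,
        "has_xy": not np.isnan(x),
    }


class TestFilterPositions:
    def test_exact_duplicates_collapse_to_one(self, flat_lake):
        df = pd.DataFrame([
            fix("a", "2015-06-01 12:00:00", 0, 0, 5),
            fix("a", "2015-06-01 12:00:00", 0, 0, 5),
            fix("a", "2015-06-01 12:00:25", 1, 0, 5),
        ])
        out = filter_positions(df, flat_lake)
        assert len(out) == 2
        assert out.attrs["filter_counts"]["duplicate"] == 1

    def test_fix_far_outside_shoreline_removed(self, flat_lake):
        df = pd.DataFrame([
            fix("a", "2015-06-01 12:00:00", 0, 0, 5),
            fix("a", "2015-06-01 12:00:25", 1000, 0, 5),  # 500 m beyond shore
        ])
        out = filter_positions(df, flat_lake, boundary_buffer=50.0)
        assert len(out) == 1
        assert out.attrs["filter_counts"]["boundary"] == 1

    def test_displaced_middle_fix_removed_by_speed_rule(self, flat_lake):
        # middle fix 300 m off implies 12 m/s to both neighbours
        df = pd.DataFrame([
            fix("a", "2015-06-01 12:00:00", 0, 0, 5),
            fix("a", "2015-06-01 12:00:25", 300, 0, 5),
            fix("a", "2015-06-01 12:00:50", 0, 0, 5),
        ])
        out = filter_positions(df, flat_lake, max_speed=2.0)
        assert len(out) == 2
        assert set(out["x"]) == {0.0}
        assert out.attrs["filter_counts"]["speed"] == 1

    def test_plausible_track_untouched_and_filter_idempotent(self, flat_lake):
        t = pd.date_range("2015-06-01", periods=50, freq="25s")
        df = pd.DataFrame([fix("a", tt, 10 * i % 40, 5, 5) for i, tt in enumerate(t)])
        once = filter_positions(df, flat_lake)
        twice = filter_positions(once, flat_lake)
        assert len(once) == len(df)
        pd.testing.assert_frame_equal(
            once.reset_index(drop=True), twice.reset_index(drop=True)
        )

    def test_empty_input_returns_empty(self, flat_lake):
        out = filter_positions(pd.DataFrame(columns=["tag_id", "timestamp", "x", "y", "depth"]),
                               flat_lake)
        assert out.empty

    def test_missing_lake_skips_boundary_with_warning(self):
        df = pd.DataFrame([fix("a", "2015-06-01", 1e6, 0, 5)])
        with pytest.warns(UserWarning, match="boundary"):
            out = filter_positions(df, None)
        assert len(out) == 1


class TestRegularize:
    def test_interval_mean_of_two_fixes(self):
        df = pd.DataFrame([
            fix("a", "2015-06-01 12:01:00", 0, 0, 4),
            fix("a", "2015-06-01 12:08:00", 10, 0, 6),
        ])
        q = regularize(df)
        assert len(q) == 1
        r = q.iloc[0]
        assert r["interval_start"] == pd.Timestamp("2015-06-01 12:00:00")
        assert (r["x"], r["y"], r["depth"]) == (5.0, 0.0, 5.0)
        assert r["n_fixes"] == 2 and r["n_depth_fixes"] == 2

    def test_depth_only_interval_has_depth_without_coordinates(self):
        df = pd.DataFrame([
            fix("a", "2015-06-01 12:01:00", depth=4),
            fix("a", "2015-06-01 12:02:00", depth=6),
            fix("a", "2015-06-01 12:03:00", depth=5),
        ])
        q = regularize(df)
        assert len(q) == 1
        assert np.isnan(q["x"].iloc[0])
        assert q["depth"].iloc[0] == pytest.approx(5.0)
        assert q["n_depth_fixes"].iloc[0] == 3 and q["n_fixes"].iloc[0] == 0

    def test_full_day_coverage_gives_exactly_96_qpositions(self):
        t = pd.date_range("2015-06-01", "2015-06-02", freq="25s", inclusive="left")
        df = pd.DataFrame([fix("a", tt, 0, 0, 5) for tt in t])
        q = regularize(df)
        assert len(q) == 96


class TestInterpolateGaps:
    def base(self):
        return pd.DataFrame([
            qpos_row("a", "2015-06-01 12:00:00", 0.0, 0.0, 5.0, n_fixes=3, n_depth=3),
            qpos_row("a", "2015-06-01 12:45:00", 60.0, 0.0, 6.0, n_fixes=3, n_depth=3),
        ])

    def test_qualifying_gap_filled_linearly(self):
        out = interpolate_gaps(self.base())
        assert len(out) == 4
        filled = out.loc[out["interpolated"]].sort_values("interval_start")
        assert list(filled["interval_start"]) == [
            pd.Timestamp("2015-06-01 12:15:00"),
            pd.Timestamp("2015-06-01 12:30:00"),
        ]
        assert np.allclose(filled["x"], [20.0, 40.0])
        assert np.allclose(filled["y"], [0.0, 0.0])
        assert np.allclose(filled["depth"], [5 + 1 / 3, 5 + 2 / 3])
        assert (filled["n_fixes"] == 0).all()

    def test_gap_of_three_hours_not_filled(self):
        df = self.base()
        df.loc[1, "interval_start"] = pd.Timestamp("2015-06-01 15:00:00")
        out = interpolate_gaps(df)
        assert len(out) == 2

    def test_distant_endpoints_not_filled(self):
        df = self.base()
        df.loc[1, "x"] = 150.0
        out = interpolate_gaps(df)
        assert len(out) == 2

    def test_large_depth_change_not_filled(self):
        df = self.base()
        df.loc[1, "depth"] = 7.5
        out = interpolate_gaps(df)
        assert len(out) == 2

    def test_endpoint_without_coordinates_not_filled(self):
        df = self.base()
        df.loc[1, "x"] = np.nan
        df.loc[1, "y"] = np.nan
        out = interpolate_gaps(df)
        assert len(out) == 2

    def test_interpolation_idempotent_and_on_segment(self):
        once = interpolate_gaps(self.base())
        twice = interpolate_gaps(once)
        pd.testing.assert_frame_equal(once, twice)
        filled = once.loc[once["interpolated"]]
        # collinear with the bracketing q-positions
        assert np.allclose(filled["y"], 0.0)
        assert ((filled["x"] > 0) & (filled["x"] < 60)).all()


class TestDistanceToBottom:
    def test_subtraction_and_zero_at_bottom(self, flat_lake):
        q = pd.DataFrame([
            qpos_row("a", "2015-06-01 12:00:00", 0.0, 0.0, 3.0),
            qpos_row("a", "2015-06-01 12:15:00", 0.0, 0.0, 10.0),
        ])
        out = distance_to_bottom(q, flat_lake)
        assert out["dist_to_bottom"].tolist() == [7.0, 0.0]

    def test_raw_interval_uses_mean_of_per_fix_distances(self, flat_lake):
        fixes = pd.DataFrame([
            fix("a", "2015-06-01 12:01:00", 0, 0, 6.0),   # d2b 4
            fix("a", "2015-06-01 12:02:00", 0, 0, 4.0),   # d2b 6
        ])
        q = regularize(fixes)
        out = distance_to_bottom(q, flat_lake, fixes=fixes)
        assert out["dist_to_bottom"].iloc[0] == pytest.approx(5.0)

    def test_off_raster_position_kept_with_nan_and_warning(self, flat_lake):
        q = pd.DataFrame([qpos_row("a", "2015-06-01 12:00:00", 1e6, 1e6, 3.0)])
        with pytest.warns(UserWarning, match="raster"):
            out = distance_to_bottom(q, flat_lake)
        assert len(out) == 1 and np.isnan(out["dist_to_bottom"].iloc[0])


class TestFlagMortality:
    def _series(self, n, x, y, depth, start="2015-06-01"):
        t = pd.date_range(start, periods=n, freq="900s")
        return pd.DataFrame([
            qpos_row("a", tt, xx, yy, dd)
            for tt, xx, yy, dd in zip(t, np.broadcast_to(x, n),
                                      np.broadcast_to(y, n), np.broadcast_to(depth, n))
        ])

    def test_terminally_constant_track_flagged_at_onset(self):
        rng = np.random.default_rng(1)
        n_move, n_dead = 96 * 2, 96 * 5  # 2 moving days then 5 constant days
        moving = self._series(n_move, rng.uniform(0, 400, n_move),
                              rng.uniform(0, 400, n_move), rng.uniform(2, 8, n_move))
        dead = self._series(n_dead, 100.0, 100.0, 5.0)
        dead["interval_start"] = moving["interval_start"].iloc[-1] + pd.to_timedelta(
            np.arange(1, n_dead + 1) * 900, unit="s")
        v = flag_mortality(pd.concat([moving, dead], ignore_index=True))
        assert bool(v["flagged"].iloc[0])
        assert v["onset"].iloc[0] == dead["interval_start"].iloc[0]

    def test_continuously_moving_track_not_flagged(self):
        rng = np.random.default_rng(2)
        n = 96 * 5
        df = self._series(n, rng.uniform(0, 400, n), rng.uniform(0, 400, n),
                          rng.uniform(2, 8, n))
        assert not flag_mortality(df)["flagged"].iloc[0]

    def test_constancy_followed_by_movement_not_flagged(self):
        rng = np.random.default_rng(3)
        n_dead, n_move = 96, 96 * 2  # constant 24 h, then movement resumes
        dead = self._series(n_dead, 100.0, 100.0, 5.0)
        moving = self._series(n_move, rng.uniform(0, 400, n_move),
                              rng.uniform(0, 400, n_move), rng.uniform(2, 8, n_move))
        moving["interval_start"] = dead["interval_start"].iloc[-1] + pd.to_timedelta(
            np.arange(1, n_move + 1) * 900, unit="s")
        v = flag_mortality(pd.concat([dead, moving], ignore_index=True))
        assert not v["flagged"].iloc[0]

    def test_short_terminal_constancy_below_window_not_flagged(self):
        rng = np.random.default_rng(4)
        n_move, n_dead = 96 * 3, 48  # only 12 h constant
        moving = self._series(n_move, rng.uniform(0, 400, n_move),
                              rng.uniform(0, 400, n_move), rng.uniform(2, 8, n_move))
        dead = self._series(n_dead, 100.0, 100.0, 5.0)
        dead["interval_start"] = moving["interval_start"].iloc[-1] + pd.to_timedelta(
            np.arange(1, n_dead + 1) * 900, unit="s")
        v = flag_mortality(pd.concat([moving, dead], ignore_index=True))
        assert not v["flagged"].iloc[0]


def test_noise_free_round_trip_matches_true_interval_means(small_lake):
    """Regularized q-positions equal 15-min means of the true track exactly
    when every burst is detected without noise."""
    fish = lt.FishSpec("f1", 80, 4, "TST", "cruise", (0, 0))
    truth = lt.simulate_track(small_lake, fish, "2015-06-01", "2015-06-02", seed=21)
    obs = lt.observe_track(truth, lt.ObservationModel(), seed=22, tag_id="f1")
    q = regularize(obs)
    expected = (
        truth.assign(interval=truth["time"].dt.floor("900s"))
        .groupby("interval")[["x", "y", "depth"]]
        .mean()
    )
    assert len(q) == len(expected)
    assert np.allclose(q["x"].to_numpy(), expected["x"].to_numpy(), atol=1e-6)
    assert np.allclose(q["y"].to_numpy(), expected["y"].to_numpy(), atol=1e-6)
    assert np.allclose(q["depth"].to_numpy(), expected["depth"].to_numpy(), atol=1e-6)
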