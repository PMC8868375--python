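"""Behavioral statistics: distances, sleep, angles, heatmaps, regions."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from flyarena import behavior
from flyarena.arenas import ArenaLayout, TrajectorySet


def make_traj(x, y, fps=1.0, heading=None, valid=None):
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if heading is None:
        heading = np.full_like(x, np.nan)
    if valid is None:
        valid = np.ones(x.shape, dtype=bool)
    return TrajectorySet(x=x, y=y, heading=np.atleast_2d(heading), valid=valid, fps=fps)


def centered_layout(r=50.0):
    return ArenaLayout(np.array([[0.0, 0.0]]), np.array([r]))


class TestBinDistances:
    def test_closed_form_constant_speed(self):
        # 2 px/frame at 30 fps over a 600 s bin: 600*30 frames of 2 px
        n = 18000 + 1
        x = 2.0 * np.arange(n)
        df = behavior.bin_distances(make_traj(x, np.zeros(n), fps=30.0), dist_bin=600)
        assert len(df) == 1
        # frame 0 contributes no displacement, hence one step short of 36,000
        assert df["distance_px"].iloc[0] == pytest.approx(2 * 17999)

    def test_stationary_all_zero(self):
        df = behavior.bin_distances(make_traj(np.zeros(100), np.zeros(100), fps=10), dist_bin=2)
        assert (df["distance_px"] == 0).all()

    def test_three_four_five_path(self):
        df = behavior.bin_distances(make_traj([0, 3, 3], [0, 4, 4], fps=1), dist_bin=3)
        assert df["distance_px"].iloc[0] == pytest.approx(5.0)

    def test_trailing_partial_bin_dropped(self):
        df = behavior.bin_distances(make_traj(np.arange(25.0), np.zeros(25), fps=1), dist_bin=10)
        assert list(df["bin"]) == [0, 1]

    def test_subadditivity_exact(self):
        """Total distance over the union path equals the sum over bins."""
        rng = np.random.default_rng(0)
        x = np.cumsum(rng.normal(0, 2, 40))
        y = np.cumsum(rng.normal(0, 2, 40))
        whole = behavior.bin_distances(make_traj(x, y, fps=1), dist_bin=40)["distance_px"].sum()
        parts = behavior.bin_distances(make_traj(x, y, fps=1), dist_bin=10)["distance_px"].sum()
        assert parts == pytest.approx(whole)

    def test_mm_column_added_alongside(self):
        df = behavior.bin_distances(make_traj([0, 3], [0, 4], fps=1), dist_bin=2, mm_per_px=0.1)
        assert df["distance_px"].iloc[0] == pytest.approx(5.0)
        assert df["distance_mm"].iloc[0] == pytest.approx(0.5)


class TestDetectSleep:
    def _traj_with_still(self, still_s, fps=1.0, pre=10, post=10):
        # moving, then still for still_s seconds, then moving again
        n_still = int(still_s * fps)
        xs = list(range(pre)) + [pre - 1] * n_still + list(range(pre, pre + post))
        return make_traj(xs, np.zeros(len(xs)), fps=fps)

    def test_360s_still_is_one_bout(self):
        bouts = behavior.detect_sleep(self._traj_with_still(360), sleep_min_duration=300)
        assert len(bouts[0]) == 1
        s, e = bouts[0][0]
        assert e - s == 360

    def test_exactly_300s_is_not_sleep(self):
        """Immobility of exactly the 5-min threshold does not qualify (strict rule)."""
        bouts = behavior.detect_sleep(self._traj_with_still(300), sleep_min_duration=300)
        assert bouts[0] == []

    def test_never_still_is_empty(self):
        n = 500
        traj = make_traj(2.0 * np.arange(n), np.zeros(n), fps=1)
        assert behavior.detect_sleep(traj, sleep_min_duration=300) == [[]]

    def test_carried_invalid_frames_count_as_still(self):
        x = np.concatenate([np.arange(10.0), np.full(400, 9.0), np.arange(10.0, 20.0)])
        traj = make_traj(x, np.zeros_like(x), fps=1)
        bouts = behavior.detect_sleep(traj, sleep_min_duration=300)
        assert len(bouts[0]) == 1


class TestSleepStatus:
    def test_direct_arithmetic_cases(self):
        gt = pd.DataFrame({"fly_id": [0, 1], "group": ["g", "g"]})
        fc, fps, sbin = 1000, 1.0, 1000.0
        # all asleep the entire bin
        bouts = [[(0, 1000)], [(0, 1000)]]
        df = behavior.sleep_status(bouts, gt, sbin, fps, fc)
        assert df["mean_sleep_s"].iloc[0] == pytest.approx(1000.0)
        assert df["frac_asleep"].iloc[0] == 1.0
        # no bouts anywhere
        df0 = behavior.sleep_status([[], []], gt, sbin, fps, fc)
        assert df0["mean_sleep_s"].iloc[0] == 0.0
        assert df0["frac_asleep"].iloc[0] == 0.0
        # one of two flies asleep for half the bin: mean = bin/4, fraction 1/2
        df1 = behavior.sleep_status([[(0, 500)], []], gt, sbin, fps, fc)
        assert df1["mean_sleep_s"].iloc[0] == pytest.approx(250.0)
        assert df1["frac_asleep"].iloc[0] == 0.5

    def test_unknown_arena_in_group_table_errors(self):
        gt = pd.DataFrame({"fly_id": [0, 7], "group": ["g", "g"]})
        with pytest.raises(ValueError, match="no trajectory"):
            behavior.sleep_status([[]], gt, 10, 1.0, 100)


class TestAngleChange:
    def test_straight_line_is_zero(self):
        n = 61
        traj = make_traj(3.0 * np.arange(n), np.zeros(n), fps=1)
        assert behavior.mean_angle_change(traj).iloc[0] == pytest.approx(0.0)

    def test_uniform_circular_motion(self):
        """A fly circling at 6 deg/s angular rate turns its path 6 deg each second."""
        fps, secs, omega, r = 5.0, 120, 6.0, 40.0
        t = np.arange(int(fps * secs)) / fps
        ang = np.radians(omega * t)
        traj = make_traj(r * np.cos(ang), r * np.sin(ang), fps=fps)
        got = behavior.mean_angle_change(traj).iloc[0]
        assert got == pytest.approx(6.0, rel=0.01)

    def test_stationary_fly_reports_missing_not_zero(self):
        traj = make_traj(np.zeros(100), np.zeros(100), fps=1)
        assert np.isnan(behavior.mean_angle_change(traj).iloc[0])

    def test_values_bounded(self):
        rng = np.random.default_rng(5)
        traj = make_traj(np.cumsum(rng.normal(0, 3, 300)), np.cumsum(rng.normal(0, 3, 300)), fps=1)
        df = behavior.angle_change(traj)
        assert df["change_deg"].between(0, 180).all()


class TestHeatmaps:
    def test_stationary_conservation(self):
        traj = make_traj(np.full(1000, 3.0), np.full(1000, -2.0), fps=1)
        grids = behavior.occupancy_heatmap(traj, centered_layout())
        assert grids[0].sum() == 1000
        assert grids[0].max() == 1000

    def test_remove_sleep_full_bout_empties_grid(self):
        traj = make_traj(np.zeros(1000), np.zeros(1000), fps=1)
        bouts = [[(0, 1000)]]
        grids = behavior.occupancy_heatmap(traj, centered_layout(), remove_sleep=True, all_bouts=bouts)
        assert grids[0].sum() == 0

    def test_remove_sleep_subtracts_exactly_bout_frames(self):
        rng = np.random.default_rng(7)
        n = 400
        traj = make_traj(rng.uniform(-20, 20, n), rng.uniform(-20, 20, n), fps=1)
        bouts = [[(50, 120), (300, 350)]]
        full = behavior.occupancy_heatmap(traj, centered_layout())
        cut = behavior.occupancy_heatmap(traj, centered_layout(), remove_sleep=True, all_bouts=bouts)
        assert full[0].sum() - cut[0].sum() == 120 - 50 + 350 - 300

    def test_rim_circling_confined_to_annulus(self):
        r = 50.0
        t = np.linspace(0, 4 * np.pi, 2000)
        traj = make_traj(0.9 * r * np.cos(t), 0.9 * r * np.sin(t), fps=1)
        grid = behavior.occupancy_heatmap(traj, centered_layout(r))[0]
        side = grid.shape[0]
        yy, xx = np.mgrid[0:side, 0:side]
        rho = np.hypot(xx - side // 2, yy - side // 2)
        assert grid[(rho < 0.85 * r) | (rho > 0.95 * r)].sum() == 0
        assert grid.sum() == 2000

    def test_group_heatmap_sums_members(self):
        rng = np.random.default_rng(8)
        xy = rng.uniform(-20, 20, (2, 2, 100))
        traj = TrajectorySet(x=xy[0], y=xy[1] * 0, heading=np.full((2, 100), np.nan),
                             valid=np.ones((2, 100), dtype=bool), fps=1.0)
        layout = ArenaLayout(np.zeros((2, 2)), np.full(2, 50.0))
        grids = behavior.occupancy_heatmap(traj, layout)
        gt = pd.DataFrame({"fly_id": [0, 1], "group": ["g", "g"]})
        gmap = behavior.group_heatmap(grids, gt)
        assert gmap["g"].sum() == 200
        np.testing.assert_array_equal(gmap["g"], grids[0] + grids[1])


class TestRegionalPreference:
    def test_center_fixed(self):
        traj = make_traj(np.zeros(100), np.zeros(100), fps=1)
        df = behavior.regional_preference(traj, centered_layout(), k=3)
        assert df["fraction"].iloc[0] == 1.0

    def test_rim_circling_in_outer_bin(self):
        t = np.linspace(0, 2 * np.pi, 500)
        traj = make_traj(45 * np.cos(t), 45 * np.sin(t), fps=1)
        df = behavior.regional_preference(traj, centered_layout(50.0), k=3)
        assert df[df["radial_bin"] == 2]["fraction"].iloc[0] == 1.0

    def test_uniform_disc_matches_annulus_areas(self):
        """Monte-Carlo oracle: uniform points fall per bin proportionally to annulus area."""
        rng = np.random.default_rng(9)
        n = 40_000
        rho = 50.0 * np.sqrt(rng.uniform(size=n))
        phi = rng.uniform(0, 2 * np.pi, n)
        traj = make_traj(rho * np.cos(phi), rho * np.sin(phi), fps=1)
        df = behavior.regional_preference(traj, centered_layout(50.0), k=3)
        expected = np.array([1, 3, 5]) / 9.0  # ((b+1)^2 - b^2) / k^2
        got = df.sort_values("radial_bin")["fraction"].to_numpy()
        np.testing.assert_allclose(got, expected, atol=0.01)

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(10)
        traj = make_traj(rng.uniform(-40, 40, 200), rng.uniform(-40, 40, 200), fps=1)
        df = behavior.regional_preference(traj, centered_layout(), k=5)
        assert df["fraction"].sum() == pytest.approx(1.0, abs=1e-9)


def test_statistics_permutation_equivariant():
    """Relabeling arenas permutes per-fly statistics identically."""
    rng = np.random.default_rng(11)
    x = np.cumsum(rng.normal(0, 2, (3, 120)), axis=1)
    y = np.cumsum(rng.normal(0, 2, (3, 120)), axis=1)
    traj = TrajectorySet(x=x, y=y, heading=np.full((3, 120), np.nan),
                         valid=np.ones((3, 120), dtype=bool), fps=1.0)
    perm = [2, 0, 1]
    traj_p = TrajectorySet(x=x[perm], y=y[perm], heading=np.full((3, 120), np.nan),
                           valid=np.ones((3, 120), dtype=bool), fps=1.0)
    d = behavior.bin_distances(traj, 30).groupby("arena")["distance_px"].sum()
    dp = behavior.bin_distances(traj_p, 30).groupby("arena")["distance_px"].sum()
    for new, old in enumerate(perm):
        assert dp[new] == pytest.approx(d[old])
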