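import numpy as np
import pandas as pd
import pytest

from feedkit import (
    EventSeries,
    OccupancyIntervals,
    bin_index,
    classify_pattern,
    filter_interpolate,
    occupancy_heatmap,
    posture_trajectory,
    simulate_pose,
    temporal_density,
)
from feedkit.synthetic import random_session_spec

from conftest import make_track


def _thin(times):
    keep = np.concatenate([[True], np.diff(times) > 0.5])
    return times[keep]


def _events(times, duration=1200.0, min_interval=0.5):
    ev = pd.DataFrame(
        {"time_s": times, "hand": "right", "kind": "tray_entry", "tray_id": -1}
    )
    return EventSeries(events=ev, duration=duration, min_interval=min_interval)


class TestBinIndex:
    def test_event_counts_by_timestamp(self):
        binned = bin_index(_events([10.0, 310.0, 1190.0]))
        assert binned.values.tolist() == [1.0, 1.0, 0.0, 1.0]
        assert binned.kind == "count"

    def test_interval_split_at_bin_boundary(self):
        occ = OccupancyIntervals(intervals=[(290.0, 310.0)], duration=1200.0)
        binned = bin_index(occ)
        assert binned.values.tolist() == [10.0, 10.0, 0.0, 0.0]

    def test_partial_last_bin_warns(self):
        with pytest.warns(UserWarning, match="partial"):
            binned = bin_index(_events([100.0], duration=1000.0), duration=1000.0)
        assert binned.n_bins == 4
        assert binned.bin_edges[-1] == 1000.0

    def test_nonpositive_bin_rejected(self):
        with pytest.raises(ValueError):
            bin_index(_events([1.0]), bin_width=0)

    @pytest.mark.parametrize("seed", range(5))
    def test_count_and_duration_conservation(self, seed):
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(0, 1199, 40))
        times = _thin(times)
        binned = bin_index(_events(times))
        assert binned.values.sum() == len(times)
        bounds = np.sort(rng.uniform(0, 1200, 12))
        occ = OccupancyIntervals(
            intervals=list(zip(bounds[::2], bounds[1::2])), duration=1200.0
        )
        binned_d = bin_index(occ)
        assert binned_d.values.sum() == pytest.approx(occ.total)


class TestClassifyPattern:
    @pytest.mark.parametrize(
        "bins,label",
        [
            ((10, 2, 1, 0), "early_decline"),
            ((2, 8, 9, 3), "mid_peak_early_incline"),
            ((5, 5, 5, 1), "late_decline"),
            ((8, 6, 4, 3), "steady_decline"),
        ],
    )
    def test_canonical_shapes(self, bins, label):
        assert classify_pattern(bins) == label

    def test_all_zero_unclassified(self):
        assert classify_pattern((0, 0, 0, 0)) == "unclassified"

    def test_non_monotone_without_peak_unclassified(self):
        assert classify_pattern((5, 4, 5, 5)) == "unclassified"

    def test_early_decline_takes_precedence_over_steady(self):
        # monotone non-increasing AND sharp first drop: early wins
        assert classify_pattern((10, 4, 3, 2)) == "early_decline"

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            classify_pattern((1, 2, 3))


class TestTemporalDensity:
    def test_uniform_events_in_first_window(self):
        times = np.linspace(0.5, 4.5, 10)
        dens = temporal_density(
            _events(times, duration=20.0, min_interval=0.1), window=5.0, fps=30
        )
        assert dens.density[0] == pytest.approx(2.0)

    def test_no_events_zero_trace(self):
        dens = temporal_density(_events([], duration=20.0), window=5.0, fps=30)
        assert np.all(dens.density == 0)

    def test_truncated_final_window_uses_actual_length(self):
        # one event at 19.5 s of a 20 s session: at t=19 s the window is 1 s
        dens = temporal_density(_events([19.5], duration=20.0), window=5.0, fps=30)
        i = int(19.0 * 30)
        assert dens.density[i] == pytest.approx(1.0 / 1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_brute_force_window_counts(self, seed):
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(0, 60, 25))
        times = _thin(times)
        duration = 60.0
        dens = temporal_density(_events(times, duration), window=5.0, fps=30)
        for i in range(0, len(dens.times), 17):
            t = dens.times[i]
            count = np.sum((times >= t) & (times < t + 5.0))
            eff = min(5.0, duration - t)
            assert dens.density[i] == pytest.approx(count / eff)

    @pytest.mark.parametrize("seed", range(5))
    def test_integral_recovers_event_count(self, seed):
        rng = np.random.default_rng(seed)
        times = np.sort(rng.uniform(0, 1199.5, 60))
        times = _thin(times)
        dens = temporal_density(_events(times), window=5.0, fps=30)
        assert dens.integrate() == pytest.approx(len(times), abs=1e-9)


class TestOccupancyHeatmap:
    def test_stationary_keypoint_single_cell(self):
        n = 100
        track = make_track(
            {"body_center": (np.full(n, 320.0), np.full(n, 240.0), np.ones(n))}
        )
        grid = occupancy_heatmap(track, extent=(0, 640, 0, 480))
        assert grid.grid.max() == pytest.approx(1.0)
        assert (grid.grid > 0).sum() == 1

    def test_half_time_in_each_of_two_cells(self):
        n = 100
        x = np.where(np.arange(n) < 50, 100.0, 500.0)
        track = make_track({"body_center": (x, np.full(n, 240.0), np.ones(n))})
        grid = occupancy_heatmap(track, grid_shape=(1, 2), extent=(0, 640, 0, 480))
        assert grid.grid.flatten().tolist() == pytest.approx([0.5, 0.5])

    def test_degenerate_extent_rejected(self):
        n = 10
        track = make_track(
            {"body_center": (np.full(n, 1.0), np.full(n, 1.0), np.ones(n))}
        )
        with pytest.raises(ValueError, match="degenerate"):
            occupancy_heatmap(track)

    @pytest.mark.parametrize("seed", range(3))
    def test_random_walk_proportions_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        n = 2000
        x = np.clip(np.cumsum(rng.normal(0, 5, n)) + 320, 1, 639)
        y = np.clip(np.cumsum(rng.normal(0, 5, n)) + 240, 1, 479)
        track = make_track({"body_center": (x, y, np.ones(n))})
        grid = occupancy_heatmap(track, extent=(0, 640, 0, 480))
        assert grid.grid.sum() == pytest.approx(1.0, abs=1e-9)

    def test_refinement_nests_into_coarse_cells(self):
        rng = np.random.default_rng(5)
        n = 1000
        x = rng.uniform(1, 639, n)
        y = rng.uniform(1, 479, n)
        track = make_track({"body_center": (x, y, np.ones(n))})
        coarse = occupancy_heatmap(track, grid_shape=(10, 10), extent=(0, 640, 0, 480))
        fine = occupancy_heatmap(track, grid_shape=(40, 40), extent=(0, 640, 0, 480))
        merged = fine.grid.reshape(10, 4, 10, 4).sum(axis=(1, 3))
        np.testing.assert_allclose(merged, coarse.grid, atol=1e-12)


class TestPostureTrajectory:
    def test_constant_positions_give_identical_steps(self):
        n = 90 * 30
        parts = {
            p: (np.full(n, float(i * 10 + 5)), np.full(n, float(i * 20 + 5)), np.ones(n))
            for i, p in enumerate(("head_top", "mouth", "body_center"))
        }
        traj = posture_trajectory(make_track(parts))
        assert traj.n_steps == 60
        for p in ("head_top", "mouth", "body_center"):
            assert np.ptp(traj.points[p], axis=0).max() == 0.0
        assert len(traj.segments()) == 120

    def test_linear_motion_averages_at_second_midpoints(self):
        n = 70 * 30
        t = np.arange(n) / 30
        parts = {
            p: (2.0 * t, 3.0 * t, np.ones(n))
            for p in ("head_top", "mouth", "body_center")
        }
        traj = posture_trajectory(make_track(parts))
        # mean of a linear signal over second k is its value at the midpoint
        mids = np.arange(60) + 0.5 - 1 / 60  # frame-grid midpoint of each second
        np.testing.assert_allclose(traj.points["mouth"][:, 0], 2.0 * mids, atol=1e-9)

    def test_matches_brute_force_means(self):
        rng = np.random.default_rng(3)
        n = 65 * 30
        parts = {
            p: (rng.uniform(0, 640, n), rng.uniform(0, 480, n), np.ones(n))
            for p in ("head_top", "mouth", "body_center")
        }
        track = make_track(parts)
        traj = posture_trajectory(track)
        for p in ("head_top", "mouth", "body_center"):
            xy = track.xy(p)
            for k in range(60):
                np.testing.assert_allclose(
                    traj.points[p][k], xy[k * 30 : (k + 1) * 30].mean(axis=0)
                )

    def test_window_longer_than_session_truncates_with_warning(self):
        n = 30 * 30
        parts = {
            p: (np.zeros(n), np.zeros(n), np.ones(n))
            for p in ("head_top", "mouth", "body_center")
        }
        with pytest.warns(UserWarning, match="truncated"):
            traj = posture_trajectory(make_track(parts), window=60.0)
        assert traj.n_steps == 30

    def test_trailing_trace_keeps_raw_frames(self):
        spec = random_session_spec(seed=1, duration=70.0)
        track, _ = simulate_pose(spec)
        traj = posture_trajectory(
            filter_interpolate(track, 0.7), trailing=0.3
        )
        assert traj.trailing is not None
        assert len(traj.trailing["mouth"]) == 60 * 30
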