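import numpy as np
import pytest

from feedkit import (
    SynthSpec,
    detect_bouts,
    detect_entries,
    filter_interpolate,
    food_zone_occupancy,
    in_circle,
    simulate_pose,
    tray_approaches,
)
from feedkit.synthetic import BASE_POSITIONS, default_zone

from conftest import make_track


def brute_force_entries(inside, fps, min_interval):
    """Sequential reference implementation of the de-duplication rule."""
    kept = []
    last = None
    for f in range(len(inside)):
        is_entry = inside[f] and (f == 0 or not inside[f - 1])
        if not is_entry:
            continue
        t = f / fps
        if last is None or t - last >= min_interval:
            kept.append(t)
            last = t
    return kept


class TestInCircle:
    def test_point_at_center_inside(self):
        assert in_circle(np.array([[5.0, 5.0]]), (5.0, 5.0), 2.0)[0]

    def test_boundary_is_inclusive(self):
        assert in_circle(np.array([[7.0, 5.0]]), (5.0, 5.0), 2.0)[0]
        assert not in_circle(np.array([[7.001, 5.0]]), (5.0, 5.0), 2.0)[0]

    def test_matches_brute_force_distances(self):
        rng = np.random.default_rng(0)
        pts = rng.uniform(0, 100, size=(500, 2))
        center, radius = (40.0, 60.0), 25.0
        mask = in_circle(pts, center, radius)
        brute = np.array(
            [np.hypot(p[0] - center[0], p[1] - center[1]) <= radius for p in pts]
        )
        np.testing.assert_array_equal(mask, brute)

    def test_nonpositive_radius_rejected(self):
        with pytest.raises(ValueError):
            in_circle(np.zeros((1, 2)), (0, 0), 0.0)


class TestDetectEntries:
    def _mask(self, entry_frames, n, dwell=3):
        m = np.zeros(n, bool)
        for f in entry_frames:
            m[f : f + dwell] = True
        return m

    def test_close_pair_collapses_to_first(self):
        # transitions at 1.0 s and 1.3 s: one event at 1.0 s
        mask = self._mask([30, 39], 60)
        ev = detect_entries(mask, fps=30, min_interval=0.5)
        assert ev.times.tolist() == [1.0]

    def test_pair_beyond_interval_both_kept(self):
        mask = self._mask([30, 48], 60)
        ev = detect_entries(mask, fps=30, min_interval=0.5)
        assert ev.times.tolist() == [1.0, 1.6]

    def test_first_frame_inside_counts_at_zero(self):
        mask = np.array([True, True, False, False])
        ev = detect_entries(mask, fps=30)
        assert ev.times.tolist() == [0.0]

    def test_greedy_resets_clock_at_surviving_event(self):
        # entries at 0.0, 0.4, 0.8: 0.4 suppressed, 0.8 kept (0.8 from 0.0)
        mask = self._mask([0, 12, 24], 60, dwell=2)
        ev = detect_entries(mask, fps=30, min_interval=0.5)
        assert ev.times.tolist() == [0.0, 0.8]

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_on_random_series(self, seed):
        rng = np.random.default_rng(seed)
        inside = rng.random(400) < 0.3
        ev = detect_entries(inside, fps=30, min_interval=0.5)
        assert ev.times.tolist() == brute_force_entries(inside, 30, 0.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_output_subset_of_raw_transitions(self, seed):
        rng = np.random.default_rng(100 + seed)
        inside = rng.random(300) < 0.5
        prev = np.concatenate([[False], inside[:-1]])
        raw = set((np.flatnonzero(inside & ~prev) / 30).tolist())
        ev = detect_entries(inside, fps=30)
        assert set(ev.times.tolist()) <= raw


class TestTrayApproaches:
    def _track_with_hands(self, left_x, right_x, n, zone):
        cy = zone.tray_centers[0][1]
        parts = {}
        for name, xs in (("left_hand", left_x), ("right_hand", right_x)):
            parts[name] = (xs, np.full(n, cy), np.ones(n))
        return make_track(parts)

    def test_single_left_entry(self, zone):
        n = 90
        cx = zone.tray_centers[0][0]
        left = np.full(n, 100.0)
        left[30:45] = cx
        right = np.full(n, 100.0)
        track = self._track_with_hands(left, right, n, zone)
        clean = filter_interpolate(track, 0.7)
        ev = tray_approaches(clean, zone)
        assert len(ev) == 1
        assert ev.events.iloc[0]["hand"] == "left"
        assert ev.events.iloc[0]["time_s"] == 1.0

    def test_interval_constraint_is_per_hand(self, zone):
        # left and right enter 0.2 s apart: both count
        n = 90
        cx = zone.tray_centers[0][0]
        left = np.full(n, 100.0)
        left[30:40] = cx
        right = np.full(n, 100.0)
        right[36:46] = cx
        track = self._track_with_hands(left, right, n, zone)
        ev = tray_approaches(filter_interpolate(track, 0.7), zone)
        assert len(ev) == 2
        assert sorted(ev.events["hand"]) == ["left", "right"]

    def test_missing_hand_part_errors(self, zone):
        track = make_track({"left_hand": ([0.0], [0.0], [1.0])})
        with pytest.raises(ValueError, match="right hand"):
            tray_approaches(filter_interpolate(track, 0.7), zone)

    def test_planted_entries_recovered_per_hand(self, zone):
        spec = SynthSpec(
            duration=60.0,
            tray_entry_times={
                "left": [5.0, 15.0, 25.0],
                "right": [10.0, 20.0, 30.0],
            },
        )
        track, truth = simulate_pose(spec)
        ev = tray_approaches(filter_interpolate(track, 0.7), spec.zone)
        assert len(ev) == 6
        for hand in ("left", "right"):
            got = ev.events[ev.events["hand"] == hand]["time_s"].tolist()
            want = sorted(spec.tray_entry_times[hand])
            np.testing.assert_allclose(got, want, atol=1 / 30)


class TestFoodZoneOccupancy:
    def test_always_left_of_edge_is_empty(self, zone):
        n = 100
        track = make_track(
            {"body_center": (np.full(n, 100.0), np.zeros(n), np.ones(n))}
        )
        occ = food_zone_occupancy(filter_interpolate(track, 0.7), zone)
        assert occ.intervals == []
        assert occ.total == 0.0

    def test_first_ten_seconds_inside(self, zone):
        n = 600
        x = np.full(n, 100.0)
        x[:300] = zone.food_zone_left_edge_x + 50
        track = make_track({"body_center": (x, np.zeros(n), np.ones(n))})
        occ = food_zone_occupancy(filter_interpolate(track, 0.7), zone)
        assert occ.intervals == [(0.0, 10.0)]

    @pytest.mark.parametrize("seed", range(5))
    def test_total_matches_per_frame_count(self, zone, seed):
        rng = np.random.default_rng(seed)
        n = 900
        x = np.cumsum(rng.normal(0, 20, n)) + zone.food_zone_left_edge_x
        track = make_track({"body_center": (np.clip(x, 0, 640), np.zeros(n), np.ones(n))})
        clean = filter_interpolate(track, 0.7)
        occ = food_zone_occupancy(clean, zone)
        per_frame = (
            clean.part("body_center")["x"].to_numpy() > zone.food_zone_left_edge_x
        ).sum() / 30
        assert occ.total == pytest.approx(per_frame)


class TestDetectBouts:
    def _bout_track(self, zone, tray_time, mouth_time, n_seconds=20):
        """Right hand visits the tray then (maybe) the mouth zone."""
        n = n_seconds * 30
        mouth_pos = np.asarray(BASE_POSITIONS["mouth"])
        tray = np.asarray(zone.tray_centers[0], float)
        rest = np.array([260.0, 330.0])
        xy = np.tile(rest, (n, 1))
        kt = int(tray_time * 30)
        xy[kt : kt + 9] = tray
        km = int(mouth_time * 30)
        xy[km : km + 9] = mouth_pos
        parts = {
            "mouth": (np.full(n, mouth_pos[0]), np.full(n, mouth_pos[1]), np.ones(n)),
            "right_hand": (xy[:, 0], xy[:, 1], np.ones(n)),
            "left_hand": (np.full(n, 180.0), np.full(n, 330.0), np.ones(n)),
        }
        return make_track(parts)

    def test_mouth_entry_within_lookback_is_bout(self, zone):
        track = self._bout_track(zone, tray_time=2.0, mouth_time=4.0)
        bouts = detect_bouts(filter_interpolate(track, 0.7), zone)
        assert len(bouts) == 1
        assert bouts.events.iloc[0]["time_s"] == pytest.approx(4.0)
        assert bouts.events.iloc[0]["hand"] == "right"

    def test_mouth_entry_outside_lookback_is_not_bout(self, zone):
        track = self._bout_track(zone, tray_time=5.0, mouth_time=10.0)
        bouts = detect_bouts(filter_interpolate(track, 0.7), zone)
        assert len(bouts) == 0

    def test_duplicate_mouth_entries_deduplicated(self, zone):
        n = 20 * 30
        mouth_pos = np.asarray(BASE_POSITIONS["mouth"])
        tray = np.asarray(zone.tray_centers[0], float)
        xy = np.tile(np.array([260.0, 330.0]), (n, 1))
        xy[60:69] = tray  # tray at 2 s
        xy[120:124] = mouth_pos  # mouth entries at 4.0 and 4.2 s
        xy[126:130] = mouth_pos
        parts = {
            "mouth": (np.full(n, mouth_pos[0]), np.full(n, mouth_pos[1]), np.ones(n)),
            "right_hand": (xy[:, 0], xy[:, 1], np.ones(n)),
            "left_hand": (np.full(n, 180.0), np.full(n, 330.0), np.ones(n)),
        }
        bouts = detect_bouts(filter_interpolate(make_track(parts), 0.7), zone)
        assert len(bouts) == 1
        assert bouts.events.iloc[0]["time_s"] == pytest.approx(4.0)

    def test_lookback_requires_same_hand(self, zone):
        # left hand visits tray, right hand goes to mouth: no bout
        n = 20 * 30
        mouth_pos = np.asarray(BASE_POSITIONS["mouth"])
        tray = np.asarray(zone.tray_centers[0], float)
        left = np.tile(np.array([180.0, 330.0]), (n, 1))
        left[60:69] = tray
        right = np.tile(np.array([260.0, 330.0]), (n, 1))
        right[120:129] = mouth_pos
        parts = {
            "mouth": (np.full(n, mouth_pos[0]), np.full(n, mouth_pos[1]), np.ones(n)),
            "right_hand": (right[:, 0], right[:, 1], np.ones(n)),
            "left_hand": (left[:, 0], left[:, 1], np.ones(n)),
        }
        bouts = detect_bouts(filter_interpolate(make_track(parts), 0.7), zone)
        assert len(bouts) == 0

    def test_bouts_subset_of_planted_mouth_entries(self, planted_spec):
        track, truth = simulate_pose(planted_spec)
        clean = filter_interpolate(track, 0.7)
        bouts = detect_bouts(clean, planted_spec.zone)
        assert len(bouts) == len(truth["bouts"])
        np.testing.assert_allclose(
            np.sort(bouts.times), np.sort(truth["bouts"].times), atol=1 / 30
        )
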