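"""Heuristic behavior detectors against scripted kinematics and brute-force oracles."""
import numpy as np
import pytest

from ethodev.behavior_classify import (
    ApproachParams,
    ProximityParams,
    daily_time_budget,
    detect_approaches,
    distance_traveled,
    group_membership,
    huddle_time,
    infer_nest_region,
    nest_following,
    open_exploration,
    pairwise_proximity,
    random_roi,
    roi_occupancy,
)
from ethodev.synthetic_data import SimConfig, simulate_family
from ethodev.trajectory_io import HuddleTrack, default_cage

from conftest import ADULTS, scripted_trackset

FOOD = default_cage().rois["food_hopper"]  # (0, 25.1, 19.5, 35.6)


class TestRoiOccupancy:
    def test_fifty_frames_inside_is_one_two_second_bout(self):
        pos = np.full((100, 1, 2), [5.0, 30.0])  # inside food hopper
        pos[50:] = [5.0, 5.0]
        ts = scripted_trackset(pos, animals=[ADULTS[0]])
        bouts, daily = roi_occupancy(ts, "female", "food_hopper")
        assert len(bouts) == 1
        assert bouts.total_seconds() == pytest.approx(2.0)
        assert daily[15] == pytest.approx(50 / 25 / 3600)

    def test_edge_point_counts_as_inside(self):
        pos = np.full((10, 1, 2), [FOOD[2], FOOD[1]])  # exact corner
        ts = scripted_trackset(pos, animals=[ADULTS[0]])
        _, daily = roi_occupancy(ts, "female", "food_hopper")
        assert daily[15] > 0

    def test_matches_brute_force_point_in_rectangle_scan(self):
        rng = np.random.default_rng(11)
        pos = rng.uniform([0, 0], [57.2, 35.6], size=(5000, 1, 2))
        ts = scripted_trackset(pos, animals=[ADULTS[0]])
        _, daily = roi_occupancy(ts, "female", "food_hopper")
        x0, y0, x1, y1 = FOOD
        count = sum(
            1
            for x, y in pos[:, 0]
            if x0 <= x <= x1 and y0 <= y <= y1
        )
        assert daily[15] == pytest.approx(count / 25 / 3600)

    def test_random_control_roi_inside_cage(self):
        cage = default_cage()
        rng = np.random.default_rng(0)
        for _ in range(20):
            x0, y0, x1, y1 = random_roi(cage, (19.5, 10.5), rng)
            assert 0 <= x0 < x1 <= cage.length_cm
            assert 0 <= y0 < y1 <= cage.width_cm


class TestDistanceAndOpen:
    def test_stationary_animal_travels_zero(self):
        ts = scripted_trackset(np.full((100, 1, 2), 10.0), animals=[ADULTS[0]])
        assert distance_traveled(ts, "female")[15] == 0.0

    def test_straight_100cm_path_is_one_meter(self):
        pos = np.zeros((101, 1, 2))
        pos[:, 0, 0] = np.linspace(2.0, 52.0, 101)  # two 50 cm sweeps = 100 cm
        pos[:, 0, 1] = 10.0
        pos = np.concatenate([pos, pos[::-1]], axis=0)
        ts = scripted_trackset(pos, animals=[ADULTS[0]])
        assert distance_traveled(ts, "female")[15] == pytest.approx(1.0)

    def test_random_walk_matches_cumulative_sum_oracle(self):
        rng = np.random.default_rng(5)
        steps = rng.normal(0, 0.3, size=(2000, 2))
        path = np.clip(np.cumsum(steps, axis=0) + 25.0, 1, 34)
        ts = scripted_trackset(path[:, None, :], animals=[ADULTS[0]])
        expected = np.sum(np.linalg.norm(np.diff(path, axis=0), axis=1)) / 100.0
        assert distance_traveled(ts, "female")[15] == pytest.approx(expected, rel=1e-6)

    def test_missing_frames_contribute_no_distance(self):
        pos = np.full((10, 1, 2), 10.0)
        pos[4:6] = np.nan
        pos[6:, 0, 0] = 30.0
        ts = scripted_trackset(pos, animals=[ADULTS[0]])
        assert distance_traveled(ts, "female")[15] == 0.0

    def test_open_time_excludes_nest_disc(self):
        pos = np.full((100, 1, 2), [10.0, 10.0])
        pos[50:] = [40.0, 20.0]
        ts = scripted_trackset(pos, animals=[ADULTS[0]])
        hrs = open_exploration(ts, "female", ("disc", 10.0, 10.0, 12.0))
        assert hrs[15] == pytest.approx(50 / 25 / 3600)


class TestProximity:
    def _pair(self, close_frames, dist):
        T = 40
        pos = np.empty((T, 2, 2))
        pos[:, 0] = [10.0, 10.0]
        pos[:, 1] = [10.0, 30.0]
        pos[10 : 10 + close_frames, 1] = [10.0, 10.0 + dist]
        return scripted_trackset(pos, animals=ADULTS)

    def test_320ms_below_5cm_is_a_bout(self):
        bouts = pairwise_proximity(self._pair(8, 4.9), "female", "male")
        assert len(bouts) == 1

    def test_160ms_is_too_short(self):
        assert len(pairwise_proximity(self._pair(4, 4.9), "female", "male")) == 0

    def test_exactly_5cm_is_not_close(self):
        assert len(pairwise_proximity(self._pair(8, 5.0), "female", "male")) == 0

    def test_symmetric_in_arguments(self):
        ts = self._pair(8, 4.9)
        a = pairwise_proximity(ts, "female", "male")
        b = pairwise_proximity(ts, "male", "female")
        np.testing.assert_array_equal(a.bouts, b.bouts)
        assert a.subject == b.subject

    def test_raising_distance_never_decreases_time(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform([5, 5], [50, 30], size=(500, 2, 2))
        ts = scripted_trackset(pos, animals=ADULTS)
        totals = [
            pairwise_proximity(ts, "female", "male", ProximityParams(d, 0.0)).total_seconds()
            for d in (3.0, 5.0, 8.0, 15.0, 60.0)
        ]
        assert all(b >= a for a, b in zip(totals, totals[1:]))


class TestGroups:
    def test_chain_forms_one_group(self):
        pos = np.array([[10.0, 10.0], [10.0, 14.0], [10.0, 18.0]])
        groups = group_membership(pos, ["female", "male", "pup1"])
        assert groups == [{"female", "male", "pup1"}] or groups == [
            {"pup1", "male", "female"}
        ]

    def test_distant_animals_are_singletons(self):
        pos = np.array([[5.0, 5.0], [25.0, 25.0], [50.0, 10.0]])
        groups = group_membership(pos, ["female", "male", "pup1"])
        assert sorted(len(g) for g in groups) == [1, 1, 1]

    def test_every_present_animal_in_exactly_one_group(self):
        rng = np.random.default_rng(9)
        for _ in range(25):
            pos = rng.uniform([0, 0], [57, 35], size=(6, 2))
            pos[rng.random(6) < 0.3] = np.nan
            names = ["female", "male", "pup1", "pup2", "pup3", "pup4"]
            groups = group_membership(pos, names)
            present = {n for n, p in zip(names, pos) if np.isfinite(p[0])}
            flat = [n for g in groups for n in g]
            assert sorted(flat) == sorted(present)

    def test_matches_brute_force_components(self):
        rng = np.random.default_rng(21)
        names = ["female", "male", "pup1", "pup2", "pup3", "pup4"]
        for _ in range(25):
            pos = rng.uniform([0, 0], [57, 35], size=(6, 2))
            groups = {frozenset(g) for g in group_membership(pos, names)}
            # brute force: repeated merge passes
            comps = [{i} for i in range(6)]
            changed = True
            while changed:
                changed = False
                for i in range(6):
                    for j in range(i + 1, 6):
                        if np.linalg.norm(pos[i] - pos[j]) < 5.0:
                            ci = next(c for c in comps if i in c)
                            cj = next(c for c in comps if j in c)
                            if ci is not cj:
                                comps.remove(cj)
                                ci |= cj
                                changed = True
            expected = {frozenset(names[i] for i in c) for c in comps}
            assert groups == expected


class TestApproaches:
    def _scripted(self, stop_at, fps=25.0):
        """Target parked at (5,5); initiator walks in along y=5 at 5 cm/s, then parks."""
        travel = np.arange(25.0, stop_at, -5.0 / fps)
        hold = np.full(50, stop_at)
        x = np.concatenate([np.full(20, 25.0), travel, hold])
        pos = np.empty((len(x), 2, 2))
        pos[:, 0, 0] = x
        pos[:, 0, 1] = 5.0
        pos[:, 1] = [5.0, 5.0]
        return scripted_trackset(pos, animals=ADULTS, fps=fps)

    def test_closing_run_ending_within_reach_is_one_approach(self):
        events, counts = detect_approaches(self._scripted(13.0), "female", "male")
        assert len(events) == 1
        assert counts[15] == 1.0

    def test_stopping_too_far_is_no_approach(self):
        events, _ = detect_approaches(self._scripted(17.0), "female", "male")
        assert events == []

    def test_moving_away_is_no_approach(self):
        x = np.concatenate([np.full(20, 20.0), np.arange(20.0, 40.0, 0.2), np.full(50, 40.0)])
        pos = np.empty((len(x), 2, 2))
        pos[:, 0, 0] = x
        pos[:, 0, 1] = 5.0
        pos[:, 1] = [5.0, 5.0]
        ts = scripted_trackset(pos, animals=ADULTS)
        events, _ = detect_approaches(ts, "female", "male")
        assert events == []


class TestHuddleAndNest:
    def test_missing_animal_fully_attributed_to_active_huddle(self):
        T = 8640  # 0.1 of a day at 1 fps
        pos = np.full((T, 1, 2), np.nan)
        ts = scripted_trackset(pos, animals=[ADULTS[0]], fps=1.0)
        ts.coverage[15] = 0.1
        hud = HuddleTrack(np.array([[0.0, float(T), 10.0, 10.0]]))
        hours = huddle_time(ts, hud)
        assert hours.loc["female", 15] == pytest.approx(24.0)

    def test_tracked_animal_outside_radius_not_huddling(self):
        pos = np.full((100, 1, 2), [20.0, 10.0])
        ts = scripted_trackset(pos, animals=[ADULTS[0]])
        hud = HuddleTrack(np.array([[0.0, 4.0, 10.0, 10.0]]))
        assert huddle_time(ts, hud).loc["female", 15] == 0.0

    def test_simulator_huddle_hours_recovered_within_5_percent(self):
        cfg = SimConfig(fps=0.5, days=(16, 17), seed=4)
        tracks, huddles, truth = simulate_family(cfg)
        rec = huddle_time(tracks, huddles)
        for animal in tracks.animal_names:
            for day in (16, 17):
                gt = truth.budget(animal, day, "huddle_hrs")
                assert rec.loc[animal, day] == pytest.approx(gt, rel=0.05)

    def test_nest_region_is_modal_huddle_centroid(self):
        hud = HuddleTrack(
            np.array(
                [
                    [0.0, 1000.0, 10.2, 8.1],
                    [1100.0, 1200.0, 40.0, 20.0],
                    [1300.0, 2300.0, 9.8, 7.9],
                ]
            )
        )
        kind, cx, cy, r = infer_nest_region(hud)
        assert kind == "disc" and r == 12.0
        assert abs(cx - 10.0) <= 1.0 and abs(cy - 8.0) <= 1.0


class TestNestFollowing:
    def test_exit_within_window_counts(self):
        assert nest_following([100.0], [108.0]) == 1

    def test_exit_outside_window_ignored(self):
        assert nest_following([100.0], [112.0]) == 0

    def test_adult_matches_earliest_unmatched_pup(self):
        assert nest_following([100.0, 101.0], [105.0]) == 1
        assert nest_following([100.0, 101.0], [105.0, 106.0]) == 2


def test_daily_time_budget_closes_to_24h():
    """Huddle + open + nest-tracked + unattributed hours sum to 24 h/day (to 1 s)."""
    cfg = SimConfig(fps=0.5, days=(16, 17), seed=2)
    tracks, huddles, _ = simulate_family(cfg)
    nest = infer_nest_region(huddles)
    for animal in ("female", "pup1"):
        budget = daily_time_budget(tracks, huddles, nest, animal)
        totals = budget.sum(axis=1)
        assert np.allclose(totals, 24.0, atol=1.0 / 3600.0)
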