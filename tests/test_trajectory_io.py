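"""Data model, dialects and centroid/light-phase conventions."""
from datetime import time as dtime

import numpy as np
import pandas as pd
import pytest

from ethodev.trajectory_io import (
    AnimalID,
    BoutSeries,
    CageGeometry,
    DailyBehaviorMatrix,
    FormatError,
    LightSchedule,
    ValidationError,
    centroid_series,
    default_family,
    light_phase,
    load_daily_matrix,
    load_trackset,
    write_daily_matrix,
    write_trackset,
)

from conftest import ADULTS, scripted_trackset


class TestDomainTypes:
    def test_family_has_two_adults_and_named_pups(self):
        fam = default_family(4)
        assert [a.name for a in fam] == ["female", "male", "pup1", "pup2", "pup3", "pup4"]
        assert sum(a.age_class == "adult" for a in fam) == 2

    def test_unknown_animal_rejected(self):
        with pytest.raises(ValidationError):
            AnimalID("hamster", "adult")

    def test_roi_outside_cage_rejected(self):
        with pytest.raises(ValidationError):
            CageGeometry(rois={"bad": (50.0, 30.0, 60.0, 36.0)})

    def test_daily_matrix_requires_contiguous_days(self):
        df = pd.DataFrame([[1.0, 2.0]], index=["pup1"], columns=[16, 18])
        with pytest.raises(ValidationError):
            DailyBehaviorMatrix("open", "hrs/day", df)

    def test_bouts_must_not_overlap(self):
        with pytest.raises(ValidationError):
            BoutSeries("prox", "pup1", [(0.0, 5.0), (4.0, 6.0)])


class TestRoundTrip:
    def test_minimal_two_frame_file(self, tmp_path):
        pos = np.array([[[10.0, 10.0]], [[10.5, 10.2]]])
        ts = scripted_trackset(pos, animals=[ADULTS[0]])
        p = tmp_path / "t.h5"
        write_trackset(ts, p)
        back = load_trackset(p)
        assert back.n_frames == 2
        assert back.animal_names == ["female"]

    def test_full_round_trip_preserves_content(self, tmp_path, two_animal_tracks):
        p = tmp_path / "t.h5"
        write_trackset(two_animal_tracks, p)
        back = load_trackset(p)
        assert back.animal_names == two_animal_tracks.animal_names
        assert back.coverage == two_animal_tracks.coverage
        assert back.fps == two_animal_tracks.fps
        np.testing.assert_allclose(
            back.positions, two_animal_tracks.positions, atol=1e-4
        )
        np.testing.assert_allclose(back.timestamps, two_animal_tracks.timestamps, atol=1e-9)

    def test_inverted_timestamps_rejected(self, tmp_path, two_animal_tracks):
        p = tmp_path / "t.h5"
        two = two_animal_tracks
        write_trackset(two, p)
        import h5py

        with h5py.File(p, "r+") as f:
            t = f["timestamps/time_s"][()]
            del f["timestamps/time_s"]
            f["timestamps"].create_dataset("time_s", data=t[::-1])
        with pytest.raises(ValidationError):
            load_trackset(p)

    def test_wide_csv_dialect(self, tmp_path):
        df = pd.DataFrame(
            {
                "time_s": [0.0, 0.04, 0.08],
                "pnd": [15, 15, 15],
                "female_x": [1.0, 2.0, 3.0],
                "female_y": [4.0, 5.0, 6.0],
            }
        )
        p = tmp_path / "t.csv"
        df.to_csv(p, index=False)
        ts = load_trackset(p, dialect="wide-csv")
        assert ts.animal_names == ["female"]
        np.testing.assert_allclose(ts.positions[:, 0, 0], [1.0, 2.0, 3.0])

    def test_pose_export_requires_scale(self, tmp_path):
        import h5py

        p = tmp_path / "pose.h5"
        with h5py.File(p, "w") as f:
            f.create_dataset("tracks", data=np.zeros((1, 2, 6, 10)) + 50.0)
            f.create_dataset("track_names", data=np.array([b"female"]))
        with pytest.raises(FormatError, match="px_to_cm"):
            load_trackset(p, dialect="pose-export")
        with h5py.File(p, "r+") as f:
            f.attrs["px_to_cm"] = 0.1
            f.attrs["fps"] = 25.0
        ts = load_trackset(p, dialect="pose-export")
        np.testing.assert_allclose(ts.positions, 5.0)

    def test_bout_csv_round_trip(self, tmp_path):
        from ethodev.trajectory_io import load_bouts, write_bouts

        series = [
            BoutSeries("proximity", ("female", "pup1"), [(0.0, 1.5), (3.0, 4.0)]),
            BoutSeries("food_hopper", "male", [(10.0, 12.0)]),
        ]
        p = tmp_path / "bouts.csv"
        write_bouts(series, p)
        back = {(s.label, s.subject): s.bouts for s in load_bouts(p)}
        np.testing.assert_allclose(
            back[("proximity", ("female", "pup1"))], series[0].bouts
        )
        np.testing.assert_allclose(back[("food_hopper", "male")], series[1].bouts)

    def test_daily_matrix_csv_round_trip(self, tmp_path):
        df = pd.DataFrame(
            [[1.0, 2.0], [3.0, 4.0]], index=["pup1", "pup2"], columns=[16, 17]
        )
        m = DailyBehaviorMatrix("open", "hrs/day", df)
        p = tmp_path / "m.csv"
        write_daily_matrix(m, p)
        back = load_daily_matrix(p)
        pd.testing.assert_frame_equal(
            back.values.sort_index(), m.values.sort_index(), check_names=False
        )


class TestCentroid:
    def _poses(self, node_xs):
        poses = np.full((1, 1, 6, 2), np.nan)
        poses[0, 0, :, 0] = node_xs
        poses[0, 0, :, 1] = 10.0
        return poses

    def test_identical_nodes_pass_through(self):
        poses = np.full((1, 1, 6, 2), 10.0)
        ts = scripted_trackset(np.full((1, 1, 2), 10.0), animals=[ADULTS[0]], poses=poses)
        np.testing.assert_allclose(centroid_series(ts, "female")[0], [10.0, 10.0])

    def test_median_damps_single_node_error(self):
        poses = self._poses([1, 2, 3, 4, 5, 100])
        ts = scripted_trackset(np.full((1, 1, 2), 10.0), animals=[ADULTS[0]], poses=poses)
        assert centroid_series(ts, "female")[0, 0] == pytest.approx(3.5)

    def test_all_nodes_missing_gives_missing(self):
        poses = np.full((2, 1, 6, 2), 5.0)
        poses[1] = np.nan
        ts = scripted_trackset(np.full((2, 1, 2), 5.0), animals=[ADULTS[0]], poses=poses)
        cent = centroid_series(ts, "female")
        assert np.isnan(cent[1]).all() and not np.isnan(cent[0]).any()

    def test_node_order_invariance(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(5, 30, size=6)
        a = self._poses(vals)
        b = self._poses(vals[::-1])
        pos = np.full((1, 1, 2), 10.0)
        ca = centroid_series(scripted_trackset(pos, animals=[ADULTS[0]], poses=a), "female")
        cb = centroid_series(scripted_trackset(pos, animals=[ADULTS[0]], poses=b), "female")
        np.testing.assert_allclose(ca, cb)

    def test_unknown_animal_raises(self, two_animal_tracks):
        with pytest.raises(KeyError):
            centroid_series(two_animal_tracks, "pup3")


class TestLightPhase:
    @pytest.mark.parametrize(
        "clock,expect",
        [
            (dtime(8, 0), "day"),
            (dtime(20, 0), "night"),
            (dtime(7, 59, 59), "night"),
            (dtime(19, 59, 59), "day"),
            (dtime(0, 0), "night"),
        ],
    )
    def test_boundaries(self, clock, expect):
        assert light_phase(LightSchedule(), clock) == expect

    def test_partition_every_minute(self):
        sched = LightSchedule()
        for h in range(24):
            for m in (0, 30, 59):
                assert light_phase(sched, dtime(h, m)) in ("day", "night")

    def test_inverted_schedule(self):
        sched = LightSchedule(dtime(20, 0), dtime(8, 0))
        assert light_phase(sched, dtime(23, 0)) == "day"
        assert light_phase(sched, dtime(12, 0)) == "night"
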