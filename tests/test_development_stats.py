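"""Adult-normalized trajectories, K-S rapid-development flags, hull overlap, power."""
from itertools import product

import numpy as np
import pandas as pd
import pytest

from ethodev.development_stats import (
    hull_overlap,
    normalize_to_adult,
    power_at_n,
    rapid_development_days,
    shuffle_identity,
    trajectory_correlations,
)
from ethodev.synthetic_data import planted_step_matrix
from ethodev.trajectory_io import DailyBehaviorMatrix

UNIT_CUBE = np.array(list(product([0.0, 1.0], repeat=3)))


def _matrix(adult_vals=(4.0, 6.0), pup_val=1.0):
    days = list(range(27, 30))
    data = {
        "female": [adult_vals[0]] * 3,
        "male": [adult_vals[1]] * 3,
        "pup1": [pup_val] * 3,
    }
    df = pd.DataFrame(data, index=days).T
    return DailyBehaviorMatrix("open", "hrs/day", df)


class TestNormalize:
    def test_pup_value_relative_to_adult_mean(self):
        traj = normalize_to_adult(_matrix())
        assert traj.reference == 5.0
        assert traj.values.loc["pup1", 29] == pytest.approx(0.2)

    def test_pup_equal_to_reference_is_one(self):
        traj = normalize_to_adult(_matrix(pup_val=5.0))
        assert traj.values.loc["pup1", 29] == pytest.approx(1.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError, match="open"):
            normalize_to_adult(_matrix(adult_vals=(0.0, 0.0)))

    def test_round_trip_recovers_input(self):
        m = _matrix()
        traj = normalize_to_adult(m)
        back = traj.values * traj.reference
        pd.testing.assert_frame_equal(back, m.values.loc[["pup1"]], check_names=False)


class TestRapidDevelopment:
    def test_constant_series_has_no_flags(self):
        rng = np.random.default_rng(0)
        vals = pd.DataFrame(
            1.0 + rng.normal(0, 0.01, size=(12, 15)),
            index=[f"a{i}" for i in range(12)],
            columns=range(15, 30),
        )
        assert rapid_development_days(vals).flagged_days == set()

    def test_planted_step_flagged_at_step_day(self):
        m = planted_step_matrix(step_day=22, seed=1)
        flags = rapid_development_days(m)
        assert 22 in flags.flagged_days
        assert flags.p_adjusted[22] < 0.05

    def test_steep_ramp_flags_consecutive_days_until_plateau(self):
        rng = np.random.default_rng(2)
        days = list(range(15, 30))
        level = np.clip((np.array(days) - 19) * 0.5, 0.0, 3.0) + 1.0  # ramp P20-P25
        vals = pd.DataFrame(
            level[None, :] + rng.normal(0, 0.02, size=(12, 15)),
            index=[f"a{i}" for i in range(12)],
            columns=days,
        )
        flags = rapid_development_days(vals)
        assert {21, 22, 23, 24, 25} <= flags.flagged_days
        assert 29 not in flags.flagged_days

    def test_null_flag_rate_bounded_by_alpha(self):
        """Expected flags under the global null stay below alpha x days tested."""
        rng = np.random.default_rng(7)
        n_flags, n_days_tested = 0, 13
        n_sims = 1000
        for _ in range(n_sims):
            vals = pd.DataFrame(
                rng.normal(1.0, 0.1, size=(12, 15)),
                index=[f"a{i}" for i in range(12)],
                columns=range(15, 30),
            )
            n_flags += len(rapid_development_days(vals).flagged_days)
        assert n_flags / n_sims <= 0.05 * n_days_tested

    def test_small_samples_skipped_with_warning(self):
        vals = pd.DataFrame(
            [[1.0] * 15, [1.1] * 15],
            index=["a", "b"],
            columns=range(15, 30),
        )
        with pytest.warns(UserWarning):
            flags = rapid_development_days(vals)
        assert flags.flagged_days == set()


class TestHullOverlap:
    def test_identical_point_sets_overlap_fully(self):
        assert hull_overlap(UNIT_CUBE, UNIT_CUBE.copy()) == pytest.approx(100.0)

    def test_distant_clouds_do_not_overlap(self):
        assert hull_overlap(UNIT_CUBE, UNIT_CUBE + 100.0) == 0.0

    def test_half_shifted_cubes_match_closed_form_jaccard(self):
        # vol(inter)=0.5, vol(union)=1.5 -> 33.33 %
        got = hull_overlap(UNIT_CUBE, UNIT_CUBE + [0.5, 0, 0], n_pcs=3, seed=0)
        assert got == pytest.approx(100.0 / 3.0, abs=1.0)

    def test_symmetric_and_bounded(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(10, 5))
        b = rng.normal(size=(10, 5)) + 0.5
        ab = hull_overlap(a, b, seed=1)
        ba = hull_overlap(b, a, seed=1)
        assert 0.0 <= ab <= 100.0
        assert ab == pytest.approx(ba, abs=0.5)

    def test_coplanar_points_fall_back_to_two_components(self):
        sq = np.array(list(product([0.0, 1.0], repeat=2)))
        flat = np.column_stack([sq, np.zeros(4)])
        got = hull_overlap(flat, flat + [0.5, 0.0, 0.0], n_pcs=3, seed=0)
        assert got == pytest.approx(100.0 / 3.0, abs=1.5)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            hull_overlap(UNIT_CUBE[:2], UNIT_CUBE)


class TestShuffleAndCorrelations:
    def test_per_day_value_multisets_preserved(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame(rng.normal(size=(6, 8)))
        out = shuffle_identity(df, seed=3)
        for col in df.columns:
            assert sorted(out[col]) == pytest.approx(sorted(df[col]))

    def test_same_seed_same_output(self):
        df = pd.DataFrame(np.arange(24.0).reshape(6, 4))
        a = shuffle_identity(df, seed=5)
        b = shuffle_identity(df, seed=5)
        pd.testing.assert_frame_equal(a, b)

    def test_identical_trajectories_correlate_perfectly(self):
        v = np.linspace(0, 1, 10)
        mats = {"b": pd.DataFrame([v, v], index=["p1", "p2"], columns=range(15, 25))}
        table = trajectory_correlations(mats)
        assert table["r"].iloc[0] == pytest.approx(1.0)

    def test_negated_trajectory_correlates_minus_one(self):
        v = np.linspace(0, 1, 10)
        mats = {"b": pd.DataFrame([v, 1.0 - v], index=["p1", "p2"], columns=range(15, 25))}
        table = trajectory_correlations(mats)
        assert table["r"].iloc[0] == pytest.approx(-1.0)

    def test_shuffling_weakens_within_behavior_correlation(self):
        rng = np.random.default_rng(6)
        base = np.linspace(0, 1, 14)
        mats = {
            "b": pd.DataFrame(
                base[None, :] * rng.uniform(0.5, 2.0, size=(8, 1))
                + rng.normal(0, 0.02, size=(8, 14)),
                index=[f"p{i}" for i in range(8)],
                columns=range(16, 30),
            )
        }
        real = trajectory_correlations(mats)
        shuf = trajectory_correlations(mats, shuffled_seed=0)
        assert real["r"].median() > shuf["r"].median()

    def test_zero_variance_trajectory_excluded(self):
        v = np.linspace(0, 1, 10)
        mats = {
            "b": pd.DataFrame(
                [v, np.ones(10)], index=["p1", "p2"], columns=range(15, 25)
            )
        }
        with pytest.warns(UserWarning):
            table = trajectory_correlations(mats)
        assert len(table) == 0


class TestPower:
    def test_developmental_effect_at_n3_exceeds_80_percent(self):
        p = power_at_n(3, 0.0, 0.10, 1.0, 0.20, alpha=0.05, reps=10_000, seed=0)
        assert p >= 0.80

    def test_null_rejection_rate_calibrated(self):
        # Welch's test is conservative at n=3 (Satterthwaite df approximation),
        # so the null rejection rate sits below alpha but must never exceed it.
        p = power_at_n(3, 0.0, 0.10, 0.0, 0.10, alpha=0.05, reps=20_000, seed=1)
        se = np.sqrt(0.05 * 0.95 / 20_000)
        assert 0.0 < p <= 0.05 + 2 * se
        # at larger n the approximation sharpens and the size approaches alpha
        p50 = power_at_n(50, 0.0, 0.10, 0.0, 0.10, alpha=0.05, reps=20_000, seed=2)
        assert p50 == pytest.approx(0.05, abs=0.01)

    def test_large_n_saturates(self):
        p = power_at_n(100, 0.0, 0.10, 1.0, 0.20, alpha=0.05, reps=2_000, seed=2)
        assert p == pytest.approx(1.0, abs=1e-3)

    def test_too_few_reps_rejected(self):
        with pytest.raises(ValueError):
            power_at_n(3, 0.0, 0.1, 1.0, 0.2, reps=10)
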