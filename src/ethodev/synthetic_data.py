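"""Synthetic gerbil-family generator with planted, recoverable structure.

The simulator emulates the statistical structure of long-term home-cage
recordings of a gerbil family (2 adults + up to 4 pups) at 25 fps in a
35.6 x 57.2 cm cage over postnatal days P15-P30: animals alternate nest
episodes (stationary at the nest, *missing* from open-field tracks, forming
huddles whenever two or more are nested) with active bouts modelled as a
goal-directed mean-reverting random walk including scripted visits to the
food-hopper and waterspout ROIs.  Pups' daily activity budgets follow
planted developmental ramps; within-day activity follows a circadian
template that switches from arrhythmic to day-biased/crepuscular at a
planted onset day.  Recording downtime (~10%) is carved out in contiguous
blocks.  Everything is reproducible from the seed, and all planted
parameters are returned as ground truth for recovery tests.

Corruption injectors (identity swaps) and light-weight planted-value
generators for the statistics modules live here too.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter

from .track_cleanup import DEFAULT_JUMP_CM, DEFAULT_REFIT_CM, SwapEvent
from .trajectory_io import (
    HuddleTrack,
    TrackSet,
    default_cage,
    default_family,
    write_huddles,
    write_trackset,
)

__all__ = [
    "RampParams",
    "SimConfig",
    "SimGroundTruth",
    "identity_accuracy",
    "inject_id_swaps",
    "make_test_fixture",
    "planted_circadian_profiles",
    "planted_step_matrix",
    "simulate_family",
]


@dataclass(frozen=True)
class RampParams:
    """Pup developmental ramp: flat baseline, then a saturating rise.

    The planted level (as a fraction of the adult level) is ``start_frac``
    strictly before ``onset_day`` and
    ``start + (plateau - start) * (1 - exp(-(d - onset + 1) / tau_days))``
    from the onset day on, so the onset is a well-defined changepoint.
    """

    onset_day: int
    start_frac: float
    plateau_frac: float
    tau_days: float = 2.0

    def fraction(self, day: int) -> float:
        if day < self.onset_day:
            return self.start_frac
        rise = 1.0 - np.exp(-(day - self.onset_day + 1) / self.tau_days)
        return self.start_frac + (self.plateau_frac - self.start_frac) * rise


def _default_ramps() -> dict[str, RampParams]:
    # Baselines and plateaus follow the observed developmental span: pups
    # start near 0.1-0.2 of the adult level around P16 and plateau near
    # adult levels by P25-P26.
    return {
        "open": RampParams(onset_day=18, start_frac=0.16, plateau_frac=0.96),
        "food_hopper": RampParams(onset_day=19, start_frac=0.10, plateau_frac=1.0),
        "waterspout": RampParams(onset_day=19, start_frac=0.10, plateau_frac=1.0),
    }


@dataclass
class SimConfig:
    """Study-condition parameters of the synthetic family.

    Defaults mirror the recording regime: 6 animals, P15-P29, lights
    08:00-20:00, ~10% downtime.  ``fps`` defaults to 5 (the full recording
    rate is 25); all behavioral thresholds elsewhere are expressed in
    seconds and cm, so analysis results are fps-invariant.
    """

    n_pups: int = 4
    fps: float = 5.0
    days: tuple[int, int] = (15, 29)
    adult_active_hours: float = 5.4
    adult_roi_hours: dict[str, float] = field(
        default_factory=lambda: {"food_hopper": 1.4, "waterspout": 0.5}
    )
    ramps: dict[str, RampParams] = field(default_factory=_default_ramps)
    pup_circadian_onset_day: int = 20
    crepuscular_peaks_h: tuple[float, float] = (7.5, 20.0)
    crepuscular_amplitude: float = 1.5
    day_bias: float = 0.4
    nest_xy: tuple[float, float] = (10.0, 8.0)
    mean_bout_s: float = 360.0
    downtime_fraction: float = 0.10
    speed_scale_cms: float = 6.0
    nest_attraction_per_s: float = 0.5
    daily_noise_frac: float = 0.08
    seed: int = 0

    def __post_init__(self) -> None:
        if not (15 <= self.days[0] < self.days[1] <= 30):
            raise ValueError(f"days must lie within [15, 30], got {self.days}")
        if not 0 <= self.downtime_fraction < 1:
            raise ValueError("downtime_fraction must be in [0, 1)")
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        max_hours = self.adult_active_hours * max(
            max(r.plateau_frac, r.start_frac) for r in self.ramps.values()
        )
        if self.adult_active_hours > 24 or max_hours > 24:
            raise ValueError("infeasible activity budget: more than 24 h/day")


@dataclass
class SimGroundTruth:
    """Planted parameters and realized per-day budgets of one simulation."""

    budgets: pd.DataFrame  # columns: animal, pnd, behavior, value
    ramp_onsets: dict[str, int]
    circadian_onset_day: int
    huddle_log: np.ndarray  # (N, 4) start_s, end_s, cx, cy
    swap_log: list[SwapEvent] = field(default_factory=list)

    def budget(self, animal: str, day: int, behavior: str) -> float:
        b = self.budgets
        sel = (b.animal == animal) & (b.pnd == day) & (b.behavior == behavior)
        return float(b.loc[sel, "value"].iloc[0])


# ---------------------------------------------------------------------------
# scheduling helpers
# ---------------------------------------------------------------------------

def _circadian_weights(cfg: SimConfig, circadian: bool) -> np.ndarray:
    """Relative bout-start intensity per wall-clock hour (sums to 1)."""
    hours = np.arange(24) + 0.5
    w = np.ones(24)
    if circadian:
        w += cfg.day_bias * ((hours >= 8) & (hours < 20))
        for peak in cfg.crepuscular_peaks_h:
            d = np.minimum(np.abs(hours - peak), 24 - np.abs(hours - peak))
            w += cfg.crepuscular_amplitude * np.exp(-0.5 * (d / 1.5) ** 2)
    return w / w.sum()


def _place_bouts(
    rng: np.random.Generator,
    target_s: float,
    weights: np.ndarray,
    mean_bout_s: float,
) -> list[tuple[float, float]]:
    """Non-overlapping active intervals within one day totalling ~target_s."""
    placed: list[tuple[float, float]] = []
    total = 0.0
    attempts = 0
    while total < target_s and attempts < 2000:
        attempts += 1
        dur = min(rng.exponential(mean_bout_s) + 30.0, target_s - total + 30.0)
        hour = rng.choice(24, p=weights)
        start = hour * 3600.0 + rng.uniform(0, 3600.0)
        end = min(start + dur, 86400.0)
        if end - start < 10.0:
            continue
        if any(s < end and start < e for s, e in placed):
            continue
        placed.append((start, end))
        total += end - start
    return sorted(placed)


def _ou_path(
    rng: np.random.Generator,
    goals: np.ndarray,
    start: np.ndarray,
    cfg: SimConfig,
    dt: float,
    bounds: tuple[float, float],
) -> np.ndarray:
    """Mean-reverting walk toward per-frame goal points, step-bounded.

    Frame-to-frame displacement never exceeds ``5 * speed_scale_cms * dt``
    and positions stay inside the cage.
    """
    n = len(goals)
    k = min(0.6, cfg.nest_attraction_per_s * dt)
    sigma = cfg.speed_scale_cms * dt
    noise = rng.normal(0.0, sigma, size=(n, 2))
    drive = k * goals + noise
    path = np.empty((n, 2))
    for ax in range(2):
        path[:, ax] = lfilter([1.0], [1.0, -(1.0 - k)], drive[:, ax], zi=[(1.0 - k) * start[ax]])[0]
    # enforce the hard per-frame step bound, then the cage bounds (box
    # projection is 1-Lipschitz so it cannot re-inflate a step)
    max_step = 5.0 * cfg.speed_scale_cms * dt
    steps = np.diff(np.vstack([start[None, :], path]), axis=0)
    norms = np.linalg.norm(steps, axis=1, keepdims=True)
    scale = np.minimum(1.0, max_step / np.maximum(norms, 1e-12))
    path = start + np.cumsum(steps * scale, axis=0)
    path[:, 0] = np.clip(path[:, 0], 1.0, bounds[0] - 1.0)
    path[:, 1] = np.clip(path[:, 1], 1.0, bounds[1] - 1.0)
    return path


# ---------------------------------------------------------------------------
# main generator
# ---------------------------------------------------------------------------

def simulate_family(config: SimConfig) -> tuple[TrackSet, HuddleTrack, SimGroundTruth]:
    """Generate one family's TrackSet, huddle track and ground truth."""
    cfg = config
    rng = np.random.default_rng(cfg.seed)
    cage = default_cage()
    animals = default_family(cfg.n_pups)
    names = [a.name for a in animals]
    d0, d1 = cfg.days
    n_days = d1 - d0 + 1
    dt = 1.0 / cfg.fps
    frames_per_day = int(round(86400 * cfg.fps))
    T = frames_per_day * n_days
    t_all = np.arange(T, dtype=np.float64) * dt
    pnd = (d0 + np.arange(T) // frames_per_day).astype(int)

    roi_centers = {
        name: np.array([(r[0] + r[2]) / 2.0, (r[1] + r[3]) / 2.0])
        for name, r in cage.rois.items()
    }
    nest = np.array(cfg.nest_xy)
    positions = np.full((T, len(animals), 2), np.nan, dtype=np.float64)
    nest_state = np.ones((T, len(animals)), dtype=bool)
    budget_rows = []

    for ai, animal in enumerate(animals):
        is_pup = animal.age_class == "pup"
        for di in range(n_days):
            day = d0 + di
            noise = rng.lognormal(0.0, cfg.daily_noise_frac)
            frac = cfg.ramps["open"].fraction(day) if is_pup else 1.0
            active_s = min(cfg.adult_active_hours * 3600.0 * frac * noise, 20 * 3600.0)
            roi_targets = {}
            for roi in ("food_hopper", "waterspout"):
                rf = cfg.ramps[roi].fraction(day) if is_pup else 1.0
                rn = rng.lognormal(0.0, cfg.daily_noise_frac)
                roi_targets[roi] = min(
                    cfg.adult_roi_hours[roi] * 3600.0 * rf * rn, 0.6 * active_s
                )
            circadian = (not is_pup) or day >= cfg.pup_circadian_onset_day
            weights = _circadian_weights(cfg, circadian)
            bouts = _place_bouts(rng, active_s, weights, cfg.mean_bout_s)
            # carve ROI dwells out of the active bouts, longest bouts first
            dwells: list[tuple[float, float, str]] = []
            remaining = dict(roi_targets)
            for s, e in sorted(bouts, key=lambda b: b[0] - b[1]):
                cursor = s + 5.0
                for roi in ("food_hopper", "waterspout"):
                    if remaining[roi] <= 0 or cursor >= e - 5.0:
                        continue
                    take = min(remaining[roi], (e - 5.0 - cursor) * 0.6)
                    if take < 5.0:
                        continue
                    dwells.append((cursor, cursor + take, roi))
                    remaining[roi] -= take
                    cursor += take + 5.0
            day_off = di * 86400.0
            realized_active = 0.0
            realized_roi = {"food_hopper": 0.0, "waterspout": 0.0}
            for s, e in bouts:
                i0 = int(round((day_off + s) * cfg.fps))
                i1 = min(int(round((day_off + e) * cfg.fps)), T)
                if i1 <= i0:
                    continue
                goals = np.tile(
                    np.array([cage.length_cm / 2.0, cage.width_cm / 2.0]), (i1 - i0, 1)
                )
                for ds, de, roi in dwells:
                    if ds >= e or de <= s:
                        continue
                    j0 = max(int(round((day_off + ds) * cfg.fps)) - i0, 0)
                    j1 = min(int(round((day_off + de) * cfg.fps)) - i0, i1 - i0)
                    goals[j0:j1] = roi_centers[roi]
                    realized_roi[roi] += max(j1 - j0, 0) * dt
                start_pos = nest + rng.uniform(-2, 2, size=2)
                path = _ou_path(
                    rng, goals, start_pos, cfg, dt, (cage.length_cm, cage.width_cm)
                )
                positions[i0:i1, ai] = path
                nest_state[i0:i1, ai] = False
                realized_active += (i1 - i0) * dt
            budget_rows += [
                (animal.name, day, "open_hrs", realized_active / 3600.0),
                (animal.name, day, "nest_hrs", 24.0 - realized_active / 3600.0),
                (animal.name, day, "food_hopper_hrs", realized_roi["food_hopper"] / 3600.0),
                (animal.name, day, "waterspout_hrs", realized_roi["waterspout"] / 3600.0),
            ]

    # huddles: any run of frames with >= 2 nested animals
    n_nested = nest_state.sum(axis=1)
    active_huddle = n_nested >= 2
    edges = np.flatnonzero(np.diff(active_huddle.astype(np.int8)))
    starts = list(edges[~active_huddle[edges]] + 1)
    ends = list(edges[active_huddle[edges]] + 1)
    if active_huddle[0]:
        starts = [0] + starts
    if active_huddle[-1]:
        ends = ends + [T]
    huddle_iv = []
    for s, e in zip(starts, ends):
        if (e - s) * dt < 10.0:
            continue
        cx, cy = nest + rng.uniform(-1.0, 1.0, size=2)
        huddle_iv.append((t_all[s], t_all[e - 1] + dt, cx, cy))
    huddle_iv = np.array(huddle_iv).reshape(-1, 4)

    # per-animal huddle ground truth: nested while a huddle is active
    for ai, animal in enumerate(animals):
        in_huddle = nest_state[:, ai] & active_huddle
        for di in range(n_days):
            day = d0 + di
            sel = slice(di * frames_per_day, (di + 1) * frames_per_day)
            budget_rows.append(
                (animal.name, day, "huddle_hrs", in_huddle[sel].sum() * dt / 3600.0)
            )
            step = np.linalg.norm(
                np.diff(positions[sel, ai], axis=0), axis=1
            )
            budget_rows.append(
                (animal.name, day, "distance_m", np.nansum(step) / 100.0)
            )

    # recording downtime: drop one contiguous block per hour
    keep = np.ones(T, dtype=bool)
    if cfg.downtime_fraction > 0:
        gap_s = cfg.downtime_fraction * 3600.0
        for h in range(n_days * 24):
            off = rng.uniform(0, 3600.0 - gap_s)
            g0 = int(round((h * 3600.0 + off) * cfg.fps))
            g1 = min(int(round((h * 3600.0 + off + gap_s) * cfg.fps)), T)
            keep[g0:g1] = False
    coverage = {
        int(d0 + di): float(keep[di * frames_per_day : (di + 1) * frames_per_day].mean())
        for di in range(n_days)
    }

    anchor = datetime(2023, 1, 1) + pd.Timedelta(days=0)
    tracks = TrackSet(
        fps=cfg.fps,
        timestamps=t_all[keep],
        anchor=anchor,
        pnd=pnd[keep],
        animals=animals,
        positions=positions[keep],
        cage=cage,
        coverage=coverage,
        family_id=f"sim-seed{cfg.seed}",
    ).validate()
    huddles = HuddleTrack(huddle_iv)
    truth = SimGroundTruth(
        budgets=pd.DataFrame(budget_rows, columns=["animal", "pnd", "behavior", "value"]),
        ramp_onsets={k: r.onset_day for k, r in cfg.ramps.items()},
        circadian_onset_day=cfg.pup_circadian_onset_day,
        huddle_log=huddle_iv,
    )
    return tracks, huddles, truth


# ---------------------------------------------------------------------------
# corruption injection
# ---------------------------------------------------------------------------

def inject_id_swaps(
    tracks: TrackSet,
    rate_per_day: float,
    seed: int = 0,
    ensure_detectable: bool = True,
    jump_cm: float = DEFAULT_JUMP_CM,
    refit_cm: float = DEFAULT_REFIT_CM,
) -> tuple[TrackSet, list[SwapEvent]]:
    """Corrupt a TrackSet with Poisson-sampled identity swaps.

    Each injection exchanges two animals' track rows from the sampled frame
    to the session end (segment-level swaps compose exactly like real
    tracker errors).  With ``ensure_detectable`` the frame/pair draw is
    re-sampled until the swap carries the detectable signature — both
    animals tracked across the swap frame, pair separation above the jump
    threshold, and at least one of the two quasi-stationary (step below the
    refit tolerance).
    """
    if len(tracks.animals) < 2:
        raise ValueError("need at least 2 animals to swap identities")
    rng = np.random.default_rng(seed)
    out = tracks.copy()
    span_days = (tracks.timestamps[-1] - tracks.timestamps[0]) / 86400.0
    n = rng.poisson(rate_per_day * span_days)
    pos = out.positions
    T, A = pos.shape[:2]
    contiguous = np.diff(out.timestamps) <= 1.5 / out.fps
    events: list[SwapEvent] = []
    # Eligibility is computed once, vectorized, on the uncorrupted data: a
    # swap permutes rows but leaves the per-frame position multiset (hence
    # pairwise separations and steps) unchanged, so eligibility of later
    # frames is unaffected.  Swaps are then applied in chronological order,
    # tracking the row permutation, so the logged pair is exactly the
    # observed-label transposition present in the output.
    pairs = [(a, b) for a in range(A) for b in range(a + 1, A)]
    if ensure_detectable:
        step = np.linalg.norm(pos[1:] - pos[:-1], axis=-1)  # (T-1, A)
        elig_any = np.zeros(T, dtype=bool)
        elig_pairs = np.zeros((T, len(pairs)), dtype=bool)
        for k, (a, b) in enumerate(pairs):
            sep = np.linalg.norm(pos[:, a] - pos[:, b], axis=-1)  # (T,)
            ok = (
                contiguous
                & (sep[:-1] > 1.2 * jump_cm)
                & (sep[1:] > 1.2 * jump_cm)
                & (np.fmin(step[:, a], step[:, b]) < 0.8 * refit_cm)
            )
            elig_pairs[1:, k] = ok & ~np.isnan(sep[:-1]) & ~np.isnan(sep[1:])
        elig_any = elig_pairs.any(axis=1)
    targets = np.sort(rng.integers(1, T, size=n))
    perm = np.arange(A)  # perm[physical] = current row
    last_f = -10
    for tf in targets:
        f0 = max(int(tf), last_f + 3)
        if ensure_detectable:
            cand = np.flatnonzero(elig_any[f0:])
            if len(cand) == 0:
                continue
            f = f0 + int(cand[0])
            k_opts = np.flatnonzero(elig_pairs[f])
            a_phys, b_phys = pairs[int(k_opts[rng.integers(len(k_opts))])]
            a, b = int(perm[a_phys]), int(perm[b_phys])
        else:
            if f0 >= T:
                continue
            f = f0
            a, b = (int(v) for v in rng.choice(A, size=2, replace=False))
        pos[f:, [a, b]] = pos[f:, [b, a]]
        if out.poses is not None:
            out.poses[f:, [a, b]] = out.poses[f:, [b, a]]
        row_of = {int(v): i for i, v in enumerate(perm)}
        perm[row_of[a]], perm[row_of[b]] = b, a
        last_f = f
        events.append(
            SwapEvent(f, (tracks.animal_names[a], tracks.animal_names[b]), "injected")
        )
    return out, events


def identity_accuracy(tracks: TrackSet, reference: TrackSet) -> float:
    """Fraction of (frame, animal) slots whose position matches the reference.

    Both-NaN counts as a match; a swapped pair counts as two mismatches.
    """
    a, b = tracks.positions, reference.positions
    if a.shape != b.shape:
        raise ValueError("TrackSets must have identical shape")
    both_nan = np.isnan(a[..., 0]) & np.isnan(b[..., 0])
    close = np.all(np.isclose(a, b, atol=1e-9, equal_nan=True), axis=-1)
    return float(np.mean(both_nan | close))


# ---------------------------------------------------------------------------
# planted-value generators for the statistics modules
# ---------------------------------------------------------------------------

def planted_step_matrix(
    n_animals: int = 12,
    days: tuple[int, int] = (15, 29),
    step_day: int = 22,
    level_before: float = 1.0,
    level_after: float = 2.0,
    sigma: float = 0.05,
    seed: int = 0,
) -> pd.DataFrame:
    """Animal x day values with a sustained step change at ``step_day``."""
    rng = np.random.default_rng(seed)
    cols = list(range(days[0], days[1] + 1))
    base = np.where(np.array(cols) >= step_day, level_after, level_before)
    vals = base[None, :] + rng.normal(0.0, sigma, size=(n_animals, len(cols)))
    return pd.DataFrame(
        np.abs(vals), index=[f"animal{i}" for i in range(n_animals)], columns=cols
    )


def _bump_profile(peak_h: float, width_h: float = 2.0, baseline: float = 0.3) -> np.ndarray:
    hours = np.arange(24) + 0.5
    d = np.minimum(np.abs(hours - peak_h), 24 - np.abs(hours - peak_h))
    w = baseline + np.exp(-0.5 * (d / width_h) ** 2)
    return w / w.sum()


def planted_circadian_profiles(
    t1: int = 19,
    t2: int = 27,
    days: tuple[int, int] = (16, 29),
    n_animals: int = 12,
    noise: float = 0.05,
    seed: int = 0,
) -> dict[tuple[str, int], np.ndarray]:
    """Per-animal daily 24-bin profiles with a planted three-regime structure.

    Days up to ``t1`` are arrhythmic (uniform), days in ``(t1, t2]`` peak at
    20:00, and days after ``t2`` peak at 05:00, with multiplicative noise.
    """
    rng = np.random.default_rng(seed)
    uniform = np.full(24, 1.0 / 24.0)
    templates = {
        "D1": uniform,
        "D2": _bump_profile(20.0),
        "D3": _bump_profile(5.0),
    }
    out: dict[tuple[str, int], np.ndarray] = {}
    for i in range(n_animals):
        for d in range(days[0], days[1] + 1):
            tpl = templates["D1"] if d <= t1 else templates["D2"] if d <= t2 else templates["D3"]
            v = tpl * rng.lognormal(0.0, noise, size=24)
            out[(f"animal{i}", d)] = v / v.sum()
    return out


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_test_fixture(
    profile: str, out_dir: str | Path, seed: int = 0
) -> dict[str, Path]:
    """Write a small simulated dataset (canonical-h5 + CSV sidecars) to disk.

    ``tiny`` is 2 adults over 2 days; ``default`` is the full 6-animal,
    15-day family.  Both are at 5 fps and fully reproducible from the seed.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if profile == "tiny":
        cfg = SimConfig(n_pups=0, days=(16, 17), fps=5.0, seed=seed)
    elif profile == "default":
        cfg = SimConfig(seed=seed)
    else:
        raise ValueError(f"unknown fixture profile {profile!r}")
    tracks, huddles, truth = simulate_family(cfg)
    paths = {
        "tracks": out_dir / f"{profile}_tracks.h5",
        "huddles": out_dir / f"{profile}_huddles.csv",
        "ground_truth": out_dir / f"{profile}_ground_truth.csv",
    }
    write_trackset(tracks, paths["tracks"])
    write_huddles(huddles, paths["huddles"])
    truth.budgets.to_csv(paths["ground_truth"], index=False)
    return paths
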