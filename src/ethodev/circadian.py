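"""Circadian profiles and automatic detection of circadian-development transitions.

Behavior is binned into 24 wall-clock hour profiles per animal and day.  The
development of circadian structure is located by an exhaustive search for
two postnatal-day breakpoints (t1, t2) splitting the recording span into
three periods D1 = [first, t1], D2 = (t1, t2], D3 = (t2, last], maximizing
the summed Bhattacharyya distances between each animal's mean normalized
hourly profiles across the periods.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd

from .trajectory_io import BoutSeries, LightSchedule, light_phase

__all__ = [
    "CircadianProfile",
    "DevelopmentalPeriods",
    "bhattacharyya_distance",
    "day_night_proportions",
    "find_transitions",
    "hourly_profile",
]


@dataclass
class CircadianProfile:
    """Behavior amount per wall-clock hour (24 non-negative bins)."""

    hour_values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.hour_values, dtype=float)
        if v.shape != (24,):
            raise ValueError(f"a circadian profile has 24 hour bins, got shape {v.shape}")
        if np.nanmin(v) < 0:
            raise ValueError("hour values must be non-negative")
        self.hour_values = v

    @property
    def total(self) -> float:
        return float(np.nansum(self.hour_values))

    def normalized(self) -> np.ndarray:
        """Profile rescaled to sum to 1 (requires positive total)."""
        tot = self.total
        if tot <= 0:
            raise ValueError("cannot normalize an all-zero profile")
        return np.nan_to_num(self.hour_values) / tot


@dataclass
class DevelopmentalPeriods:
    """Two breakpoints (t1, t2) splitting days into D1/D2/D3 (each >= 2 days)."""

    t1: int
    t2: int
    first_day: int
    last_day: int
    objective: float = float("nan")
    degenerate: bool = False
    surface: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        ok = (
            self.first_day + 1 <= self.t1
            and self.t1 + 2 <= self.t2
            and self.t2 + 2 <= self.last_day
        )
        if not ok:
            raise ValueError(
                f"invalid breakpoints t1={self.t1}, t2={self.t2} for days "
                f"[{self.first_day}, {self.last_day}] (each period needs >= 2 days)"
            )

    @property
    def periods(self) -> tuple[range, range, range]:
        return (
            range(self.first_day, self.t1 + 1),
            range(self.t1 + 1, self.t2 + 1),
            range(self.t2 + 1, self.last_day + 1),
        )


def hourly_profile(
    bouts: BoutSeries,
    anchor_midnight_offset_s: float = 0.0,
    days: tuple[int, int] | None = None,
    day_of_time=None,
    hour_coverage: np.ndarray | None = None,
) -> CircadianProfile:
    """Accumulate bout seconds into 24 wall-clock hour bins.

    Bout mass is split proportionally across the hour bins it spans (a bout
    from 09:30 to 10:30 contributes half an hour to bin 9 and half to bin
    10), averaged over the days in range, then divided per bin by the
    recording coverage of that hour; bins with zero coverage are NaN.

    Parameters
    ----------
    bouts
        Bout series with times in seconds since the session start.
    anchor_midnight_offset_s
        Seconds from the preceding midnight to session time 0.
    days
        Optional (first, last) postnatal-day filter; requires ``day_of_time``.
    day_of_time
        Callable mapping a session time (s) to its postnatal day.
    hour_coverage
        Optional 24-vector of per-hour recording coverage fractions.
    """
    acc = np.zeros(24)
    n_days_seen: set[int] = set()
    for start, end in bouts.bouts:
        if days is not None and day_of_time is not None:
            d = int(day_of_time(start))
            if not (days[0] <= d <= days[1]):
                continue
            n_days_seen.add(d)
        t = start
        while t < end:
            wall = (t + anchor_midnight_offset_s) % 86400.0
            hour = int(wall // 3600)
            bin_end = t + (3600.0 - wall % 3600.0)
            seg = min(end, bin_end) - t
            acc[hour] += seg
            t += seg
    n_days = max(len(n_days_seen), 1)
    vals = acc / n_days
    if hour_coverage is not None:
        cov = np.asarray(hour_coverage, dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            vals = np.where(cov > 0, vals / cov, np.nan)
    return CircadianProfile(vals)


def day_night_proportions(
    profile: CircadianProfile, schedule: LightSchedule = LightSchedule()
) -> tuple[float, float]:
    """Fractions of total profile mass in the light vs dark phase (sum to 1)."""
    tot = profile.total
    if tot <= 0:
        raise ValueError("profile total is zero; proportions undefined")
    from datetime import time as dtime

    day_mass = sum(
        float(np.nan_to_num(profile.hour_values[h]))
        for h in range(24)
        if light_phase(schedule, dtime(h, 0)) == "day"
    )
    return day_mass / tot, 1.0 - day_mass / tot


def bhattacharyya_distance(
    p: np.ndarray, q: np.ndarray, regularize: bool = False
) -> float:
    """Bhattacharyya distance ``-ln sum_i sqrt(p_i q_i)`` between distributions.

    Zero iff the distributions are identical; disjoint supports give +inf
    (or a large finite value with ``regularize=True``, which adds 1e-12 to
    the Bhattacharyya coefficient).
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if p.shape != q.shape:
        raise ValueError("profiles must have the same length")
    for name, v in (("p", p), ("q", q)):
        if np.any(v < 0) or not np.isclose(v.sum(), 1.0, atol=1e-6):
            raise ValueError(f"{name} must be a normalized distribution (sum 1, >= 0)")
    bc = float(np.sum(np.sqrt(p * q)))
    if regularize:
        bc += 1e-12
    if bc <= 0:
        return float("inf")
    return float(-np.log(min(bc, 1.0)))


def find_transitions(
    daily_profiles: dict[tuple[str, int], np.ndarray],
    n_periods: int = 3,
    pair_mode: str = "adjacent",
    regularize: bool = True,
) -> DevelopmentalPeriods:
    """Exhaustively locate the two breakpoints maximizing circadian separation.

    ``daily_profiles`` maps ``(animal, postnatal_day)`` to a normalized
    24-bin profile.  For each candidate ``(t1, t2)`` with every period at
    least 2 days long, the objective is the cumulative Bhattacharyya
    distance between each animal's mean normalized profiles in successive
    periods (D1 vs D2 plus D2 vs D3; ``pair_mode="all"`` also adds the D1
    vs D3 term, but that term rewards contaminating D1 with D2-like days
    and biases the first breakpoint late, so adjacent pairs are the
    default).  Ties are broken by the lexicographically earliest (t1, t2);
    a flat objective is flagged ``degenerate``.
    """
    if n_periods != 3:
        raise NotImplementedError("only the three-period (two-breakpoint) search is supported")
    days = sorted({d for _, d in daily_profiles})
    if len(days) < 6:
        raise ValueError(f"need >= 6 days for three periods of >= 2 days, got {len(days)}")
    animals = sorted({a for a, _ in daily_profiles})
    first, last = days[0], days[-1]

    def mean_profile(animal: str, period: range) -> np.ndarray | None:
        profs = [
            daily_profiles[(animal, d)] for d in period if (animal, d) in daily_profiles
        ]
        if not profs:
            return None
        m = np.mean(profs, axis=0)
        s = m.sum()
        return m / s if s > 0 else None

    rows = []
    best = None
    for t1 in range(first + 1, last - 2):
        for t2 in range(t1 + 2, last - 1):
            periods = DevelopmentalPeriods(t1, t2, first, last).periods
            J = 0.0
            pairs = (
                list(combinations(range(3), 2)) if pair_mode == "all" else [(0, 1), (1, 2)]
            )
            for animal in animals:
                means = [mean_profile(animal, p) for p in periods]
                for i, j in pairs:
                    if means[i] is None or means[j] is None:
                        continue
                    J += bhattacharyya_distance(means[i], means[j], regularize=regularize)
            rows.append((t1, t2, J))
            if best is None or J > best[2] + 1e-12:
                best = (t1, t2, J)
    surface = pd.DataFrame(rows, columns=["t1", "t2", "J"])
    t1, t2, J = best
    degenerate = bool(np.ptp(surface["J"].to_numpy()) < 1e-9)
    return DevelopmentalPeriods(
        t1, t2, first, last, objective=J, degenerate=degenerate, surface=surface
    )
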