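"""Heuristic behavior classification from cleaned centroid tracks.

All detectors operate on per-frame median centroids and produce either bout
series (half-open intervals in seconds) or daily totals.  Daily totals are
rescaled by each day's recording coverage (``observed / coverage``) so that
days with recording downtime remain comparable.

Behaviors covered: ROI occupancy (food hopper, waterspout, random-control
ROIs), open exploration and distance traveled, pairwise proximity, group
membership (connected components under a 5 cm contact graph), approaches
(rule-based implementation of the operational definition: the initiator
starts moving, closes most of the distance to the target and stops within
one body length or on contact), nest huddling, and adults following pups
out of the nest.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory_io import (
    BoutSeries,
    CageGeometry,
    HuddleTrack,
    TrackSet,
    centroid_series,
)

__all__ = [
    "ApproachParams",
    "ProximityParams",
    "daily_time_budget",
    "detect_approaches",
    "distance_traveled",
    "group_membership",
    "group_time_daily",
    "huddle_time",
    "infer_nest_region",
    "nest_exits",
    "nest_following",
    "open_exploration",
    "pairwise_proximity",
    "random_roi",
    "roi_occupancy",
]

CONTACT_CM = 2.0  # physical-contact distance ending an approach


@dataclass(frozen=True)
class ProximityParams:
    """Pairwise proximity: closer than ``dist_cm`` for more than ``min_dur_ms``."""

    dist_cm: float = 5.0
    min_dur_ms: float = 200.0

    def __post_init__(self) -> None:
        if self.dist_cm <= 0 or self.min_dur_ms < 0:
            raise ValueError("dist_cm must be > 0 and min_dur_ms >= 0")


@dataclass(frozen=True)
class ApproachParams:
    """Approach kinematics; one gerbil length defaults to the adult 10 cm."""

    gerbil_length_cm: float = 10.0
    move_speed_cms: float = 2.0
    stop_speed_cms: float = 1.0
    min_closing_frac: float = 0.5
    smooth_frames: int = 5  # centered moving average for speed estimation

    def __post_init__(self) -> None:
        if self.stop_speed_cms >= self.move_speed_cms:
            raise ValueError("stop_speed must be below move_speed")
        if self.gerbil_length_cm <= 0:
            raise ValueError("gerbil_length_cm must be positive")


# ---------------------------------------------------------------------------
# shared helpers
# ---------------------------------------------------------------------------

def _contiguous(tracks: TrackSet) -> np.ndarray:
    """(T-1,) bool: consecutive frames not separated by recording downtime."""
    return np.diff(tracks.timestamps) <= 1.5 / tracks.fps


def _mask_runs(mask: np.ndarray, contiguous: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs [i, j) of ``mask``, broken at downtime gaps."""
    if not mask.any():
        return []
    breaks = np.zeros(len(mask), dtype=bool)
    breaks[1:] = ~contiguous
    run_id = np.cumsum((~mask) | breaks)
    runs: list[tuple[int, int]] = []
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        return []
    split = np.flatnonzero(np.diff(run_id[idx]) != 0) + 1
    for chunk in np.split(idx, split):
        runs.append((int(chunk[0]), int(chunk[-1]) + 1))
    return runs


def _runs_to_bouts(
    runs: list[tuple[int, int]], tracks: TrackSet, label: str, subject
) -> BoutSeries:
    t, fps = tracks.timestamps, tracks.fps
    bouts = [(t[i], t[j - 1] + 1.0 / fps) for i, j in runs]
    return BoutSeries(label, subject, np.array(bouts).reshape(-1, 2))


def _daily_hours(mask: np.ndarray, tracks: TrackSet) -> pd.Series:
    """Coverage-rescaled hours per postnatal day from a per-frame mask."""
    days = tracks.days()
    out = {}
    for d in days:
        sel = tracks.pnd == d
        hrs = mask[sel].sum() / tracks.fps / 3600.0
        out[int(d)] = hrs / tracks.day_coverage(d)
    return pd.Series(out, dtype=float)


def in_region(points: np.ndarray, region) -> np.ndarray:
    """Membership test for ``("rect", x0, y0, x1, y1)`` (closed) or ``("disc", cx, cy, r)``."""
    x, y = points[..., 0], points[..., 1]
    kind = region[0]
    if kind == "rect":
        _, x0, y0, x1, y1 = region
        return (x >= x0) & (x <= x1) & (y >= y0) & (y <= y1)
    if kind == "disc":
        _, cx, cy, r = region
        return (x - cx) ** 2 + (y - cy) ** 2 <= r**2
    raise ValueError(f"unknown region kind {kind!r}")


# ---------------------------------------------------------------------------
# ROI occupancy / open exploration / distance
# ---------------------------------------------------------------------------

def roi_occupancy(
    tracks: TrackSet, animal: str, roi: str | tuple[float, float, float, float]
) -> tuple[BoutSeries, pd.Series]:
    """Time an animal's centroid spends inside a closed rectangular ROI.

    Returns the bout series plus coverage-rescaled hrs/day.  ``roi`` may be
    the name of a cage ROI or an explicit ``(x0, y0, x1, y1)`` rectangle.
    """
    if isinstance(roi, str):
        name, rect = roi, tracks.cage.rois[roi]
    else:
        name, rect = "roi", tuple(roi)
    cent = centroid_series(tracks, animal)
    inside = in_region(cent, ("rect", *rect)) & ~np.isnan(cent[:, 0])
    runs = _mask_runs(inside, _contiguous(tracks))
    return _runs_to_bouts(runs, tracks, name, animal), _daily_hours(inside, tracks)


def random_roi(
    cage: CageGeometry, size: tuple[float, float], rng: np.random.Generator
) -> tuple[float, float, float, float]:
    """A control ROI of the given size placed uniformly at random in the cage."""
    w, h = size
    x0 = rng.uniform(0, cage.length_cm - w)
    y0 = rng.uniform(0, cage.width_cm - h)
    return (x0, y0, x0 + w, y0 + h)


def open_exploration(tracks: TrackSet, animal: str, nest_region) -> pd.Series:
    """Hrs/day the animal is tracked outside the nest region (coverage-rescaled)."""
    cent = centroid_series(tracks, animal)
    tracked = ~np.isnan(cent[:, 0])
    outside = tracked & ~in_region(np.nan_to_num(cent, nan=-1e6), nest_region)
    return _daily_hours(outside, tracks)


def distance_traveled(tracks: TrackSet, animal: str) -> pd.Series:
    """Total centroid path length in m/day (coverage-rescaled).

    Consecutive-frame displacements are summed; pairs spanning missing data
    or recording downtime contribute nothing.
    """
    cent = centroid_series(tracks, animal)
    step = np.linalg.norm(cent[1:] - cent[:-1], axis=-1)
    valid = ~np.isnan(step) & _contiguous(tracks)
    step = np.where(valid, step, 0.0)
    days = tracks.days()
    day_of_step = tracks.pnd[1:]
    out = {}
    for d in days:
        cm = step[day_of_step == d].sum()
        out[int(d)] = cm / 100.0 / tracks.day_coverage(d)
    return pd.Series(out, dtype=float)


# ---------------------------------------------------------------------------
# proximity and groups
# ---------------------------------------------------------------------------

def pairwise_proximity(
    tracks: TrackSet,
    animal_a: str,
    animal_b: str,
    params: ProximityParams = ProximityParams(),
) -> BoutSeries:
    """Bouts during which two animals stay strictly closer than ``dist_cm``.

    Maximal close runs lasting more than ``min_dur_ms`` become bouts; both
    thresholds are strict inequalities.
    """
    ca = centroid_series(tracks, animal_a)
    cb = centroid_series(tracks, animal_b)
    dist = np.linalg.norm(ca - cb, axis=-1)
    close = dist < params.dist_cm  # NaN distances compare False
    runs = _mask_runs(close, _contiguous(tracks))
    min_frames = params.min_dur_ms / 1000.0 * tracks.fps
    runs = [(i, j) for i, j in runs if (j - i) > min_frames]
    pair = tuple(sorted((animal_a, animal_b)))
    return _runs_to_bouts(runs, tracks, "proximity", pair)


def proximity_minutes_daily(tracks: TrackSet, bouts: BoutSeries) -> pd.Series:
    """Coverage-rescaled min/day of a proximity bout series."""
    out = {}
    t = tracks.timestamps
    for d in tracks.days():
        sel = tracks.pnd == d
        lo, hi = t[sel][0], t[sel][-1] + 1.0 / tracks.fps
        secs = 0.0
        for s, e in bouts.bouts:
            secs += max(0.0, min(e, hi) - max(s, lo))
        out[int(d)] = secs / 60.0 / tracks.day_coverage(d)
    return pd.Series(out, dtype=float)


def group_membership(
    positions: np.ndarray, names: list[str], dist_cm: float = 5.0
) -> list[set[str]]:
    """Partition the animals present at one frame into contact groups.

    Groups are connected components of the graph joining pairs strictly
    closer than ``dist_cm``; missing animals (NaN) are omitted entirely.
    """
    present = ~np.isnan(positions[:, 0])
    idx = np.flatnonzero(present)
    if len(idx) == 0:
        return []
    pts = positions[idx]
    d = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    adj = d < dist_cm
    reach = adj.copy()
    for _ in range(int(np.ceil(np.log2(max(len(idx), 2))))):
        reach = reach | (reach @ reach)
    groups, seen = [], set()
    for i in range(len(idx)):
        if i in seen:
            continue
        comp = set(np.flatnonzero(reach[i]))
        seen |= comp
        groups.append({names[idx[j]] for j in comp})
    return groups


def _closure_per_frame(pos: np.ndarray, dist_cm: float) -> np.ndarray:
    """(T, A, A) bool transitive closure of the per-frame contact graph."""
    present = ~np.isnan(pos[..., 0])
    d = np.linalg.norm(pos[:, :, None, :] - pos[:, None, :, :], axis=-1)
    with np.errstate(invalid="ignore"):
        adj = d < dist_cm
    adj &= present[:, :, None] & present[:, None, :]
    A = pos.shape[1]
    eye = np.eye(A, dtype=bool)
    reach = adj | (eye & present[:, :, None] & present[:, None, :])
    for _ in range(int(np.ceil(np.log2(max(A, 2))))):
        reach = reach | np.matmul(reach, reach)
    return reach


def group_time_daily(
    tracks: TrackSet, dist_cm: float = 5.0
) -> dict[str, pd.DataFrame]:
    """Daily per-animal hours in contact groups of size 1, 2 and 3+,
    plus hours in pup-only groups versus groups containing an adult.

    Returns a dict of animal x day DataFrames keyed by
    ``size1``, ``size2``, ``size3plus``, ``pup_only``, ``with_adult``.
    """
    pos = np.stack([centroid_series(tracks, n) for n in tracks.animal_names], axis=1)
    reach = _closure_per_frame(pos, dist_cm)
    sizes = reach.sum(axis=2)  # (T, A); 0 when animal missing
    adult_idx = [i for i, a in enumerate(tracks.animals) if a.age_class == "adult"]
    has_adult = reach[:, :, adult_idx].any(axis=2)
    names = tracks.animal_names
    masks = {
        "size1": sizes == 1,
        "size2": sizes == 2,
        "size3plus": sizes >= 3,
        "pup_only": (sizes >= 1) & ~has_adult,
        "with_adult": (sizes >= 1) & has_adult,
    }
    out = {}
    for key, m in masks.items():
        df = pd.DataFrame(
            {i: _daily_hours(m[:, j], tracks) for j, i in enumerate(names)}
        ).T
        df.index.name = None
        out[key] = df
    return out


# ---------------------------------------------------------------------------
# approaches
# ---------------------------------------------------------------------------

def _smoothed_speed(cent: np.ndarray, fps: float, window: int) -> np.ndarray:
    """Per-frame speed (cm/s) from a centered moving-average position."""
    sm = cent.copy()
    if window > 1:
        kernel = np.ones(window) / window
        for k in range(2):
            v = cent[:, k]
            filled = pd.Series(v).ffill().bfill().to_numpy()
            sm[:, k] = np.convolve(filled, kernel, mode="same")
            sm[np.isnan(v), k] = np.nan
    speed = np.full(len(cent), np.nan)
    step = np.linalg.norm(sm[1:] - sm[:-1], axis=-1) * fps
    speed[1:] = step
    return speed


def detect_approaches(
    tracks: TrackSet,
    initiator: str,
    target: str,
    params: ApproachParams = ApproachParams(),
) -> tuple[list[tuple[float, float]], pd.Series]:
    """Detect approach events of ``initiator`` toward ``target``.

    An event is a maximal movement bout of the initiator (speed above
    ``move_speed_cms``, extended until it drops below ``stop_speed_cms``)
    over which the inter-animal distance shrinks by at least
    ``min_closing_frac`` of its initial value and which ends within one
    gerbil length of the target or in physical contact.

    Returns the event intervals ``(start_s, end_s)`` and coverage-rescaled
    counts per day.
    """
    ci = centroid_series(tracks, initiator)
    ct = centroid_series(tracks, target)
    speed = _smoothed_speed(ci, tracks.fps, params.smooth_frames)
    dist = np.linalg.norm(ci - ct, axis=-1)
    contiguous = _contiguous(tracks)
    moving = speed >= params.move_speed_cms
    stopped = speed < params.stop_speed_cms
    T = len(speed)
    events = []
    i = 1
    while i < T:
        if not moving[i] or np.isnan(dist[i]):
            i += 1
            continue
        start = i
        j = i
        while j + 1 < T and not stopped[j + 1] and contiguous[j]:
            j += 1
        end = j
        d0, d1 = dist[start], dist[end]
        if (
            np.isfinite(d0)
            and np.isfinite(d1)
            and (d0 - d1) >= params.min_closing_frac * d0
            and (d1 <= params.gerbil_length_cm or d1 <= CONTACT_CM)
        ):
            events.append((float(tracks.timestamps[start]), float(tracks.timestamps[end])))
        i = end + 1
    counts = {}
    starts = np.array([s for s, _ in events])
    for d in tracks.days():
        sel = tracks.pnd == d
        lo, hi = tracks.timestamps[sel][0], tracks.timestamps[sel][-1]
        n = int(np.sum((starts >= lo) & (starts <= hi))) if len(starts) else 0
        counts[int(d)] = n / tracks.day_coverage(d)
    return events, pd.Series(counts, dtype=float)


# ---------------------------------------------------------------------------
# huddling and nest behaviors
# ---------------------------------------------------------------------------

def infer_nest_region(
    huddles: HuddleTrack, radius_cm: float = 12.0
) -> tuple[str, float, float, float]:
    """Nest region: modal huddle-centroid location dilated to a disc.

    Huddle centroids are snapped to a 1 cm grid and the duration-weighted
    mode is taken as the nest center.
    """
    if len(huddles) == 0:
        raise ValueError("cannot infer a nest region without huddle intervals")
    iv = huddles.intervals
    cells = np.round(iv[:, 2:4]).astype(int)
    dur = iv[:, 1] - iv[:, 0]
    weights: dict[tuple[int, int], float] = {}
    for (cx, cy), w in zip(map(tuple, cells), dur):
        weights[(cx, cy)] = weights.get((cx, cy), 0.0) + w
    (mx, my) = max(sorted(weights), key=lambda k: weights[k])
    return ("disc", float(mx), float(my), radius_cm)


def _huddling_mask(
    tracks: TrackSet,
    huddles: HuddleTrack,
    animal: str,
    attribution_radius_cm: float = 6.0,
    attribute_missing: bool = True,
) -> np.ndarray:
    """Per-frame bool: the animal is huddling.

    True when a huddle is active and either the animal's centroid lies
    within ``attribution_radius_cm`` of the huddle centroid, or its track is
    missing (animals vanish from open-field tracking when huddled) and
    ``attribute_missing`` is set.
    """
    cent = centroid_series(tracks, animal)
    t = tracks.timestamps
    missing = np.isnan(cent[:, 0])
    huddling = np.zeros(len(t), dtype=bool)
    for s, e, cx, cy in huddles.intervals:
        sel = (t >= s) & (t < e)
        if not sel.any():
            continue
        near = np.zeros(len(t), dtype=bool)
        d = np.linalg.norm(cent[sel] - np.array([cx, cy]), axis=-1)
        near[sel] = d <= attribution_radius_cm
        huddling |= sel & (near | (missing if attribute_missing else False))
    return huddling


def huddle_time(
    tracks: TrackSet,
    huddles: HuddleTrack,
    attribution_radius_cm: float = 6.0,
    attribute_missing: bool = True,
) -> pd.DataFrame:
    """Coverage-rescaled huddling hrs/day per animal (animal x day DataFrame)."""
    out = {}
    for name in tracks.animal_names:
        m = _huddling_mask(tracks, huddles, name, attribution_radius_cm, attribute_missing)
        out[name] = _daily_hours(m, tracks)
    df = pd.DataFrame(out).T
    df.index.name = None
    return df


def daily_time_budget(
    tracks: TrackSet,
    huddles: HuddleTrack,
    nest_region,
    animal: str,
    attribution_radius_cm: float = 6.0,
) -> pd.DataFrame:
    """Decompose each day into huddle / open / nest-tracked / unattributed hours.

    Every recorded frame lands in exactly one bucket (huddling takes
    priority over open), so after coverage rescaling the four columns sum to
    24 h on days with uniform recording coverage.
    """
    cent = centroid_series(tracks, animal)
    tracked = ~np.isnan(cent[:, 0])
    hud = _huddling_mask(tracks, huddles, animal, attribution_radius_cm)
    in_nest = in_region(np.nan_to_num(cent, nan=-1e6), nest_region) & tracked
    open_f = tracked & ~in_nest & ~hud
    nest_tracked = in_nest & ~hud
    unattributed = ~tracked & ~hud
    return pd.DataFrame(
        {
            "huddle": _daily_hours(hud, tracks),
            "open": _daily_hours(open_f, tracks),
            "nest_tracked": _daily_hours(nest_tracked, tracks),
            "unattributed": _daily_hours(unattributed, tracks),
        }
    )


def nest_exits(
    tracks: TrackSet,
    huddles: HuddleTrack,
    nest_region,
    animal: str,
    min_nest_s: float = 5.0,
) -> np.ndarray:
    """Times (s) at which the animal leaves the nest for the open field.

    The animal is "in the nest" when huddling or tracked inside the nest
    region; an exit is a transition out of a nest stay of at least
    ``min_nest_s`` into tracked open-field frames.
    """
    cent = centroid_series(tracks, animal)
    tracked = ~np.isnan(cent[:, 0])
    hud = _huddling_mask(tracks, huddles, animal)
    in_nest = hud | (in_region(np.nan_to_num(cent, nan=-1e6), nest_region) & tracked)
    contiguous = _contiguous(tracks)
    exits = []
    runs = _mask_runs(in_nest, contiguous)
    t = tracks.timestamps
    for i, j in runs:
        if t[j - 1] - t[i] < min_nest_s:
            continue
        if j < len(in_nest) and tracked[j] and contiguous[j - 1]:
            exits.append(t[j])
    return np.asarray(exits, dtype=float)


def nest_following(
    pup_exits: np.ndarray, adult_exits: np.ndarray, window_s: float = 10.0
) -> int:
    """Count adult-follows-pup nest exits.

    A pair is counted when an adult exits within ``(t, t + window_s]`` of a
    pup exit; each adult exit is matched to at most one pup exit (the
    earliest unmatched one).
    """
    pups = sorted(float(t) for t in pup_exits)
    matched = [False] * len(pups)
    count = 0
    for ta in sorted(float(t) for t in adult_exits):
        for k, tp in enumerate(pups):
            if matched[k]:
                continue
            if 0.0 < ta - tp <= window_s:
                matched[k] = True
                count += 1
                break
            if tp >= ta:
                break
    return count
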