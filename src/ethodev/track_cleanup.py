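"""Track repair: identity-switch detection/correction, gap bridging, day substitution.

Multi-animal trackers occasionally exchange the identity labels of two
animals from some frame onward ("ID switch").  The detector looks for the
characteristic signature: one animal's track makes a physically implausible
jump while another animal's new position continues the first animal's old
track almost exactly.  Corrections invert the planted/detected transpositions
exactly, so a corrupted-then-corrected session matches the original.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .trajectory_io import DailyBehaviorMatrix, HuddleTrack, TrackSet

__all__ = [
    "SwapEvent",
    "correct_id_switches",
    "detect_id_switches",
    "interpolate_gaps",
    "load_swap_log",
    "substitute_day",
    "write_swap_log",
]

#: Default jump threshold (cm per frame).  10 cm in one frame at 25 fps is
#: 2.5 m/s, well beyond gerbil locomotion, so larger jumps flag label errors.
DEFAULT_JUMP_CM = 10.0
#: Default refit tolerance: the other animal must continue the old track
#: within this distance (≈5 px at a ~0.1 cm/px overhead-camera scale).
DEFAULT_REFIT_CM = 0.5


@dataclass(frozen=True)
class SwapEvent:
    """An identity exchange between two animals starting at ``frame``."""

    frame: int
    pair: tuple[str, str]
    kind: str = "detected"  # or "injected"

    def __post_init__(self) -> None:
        a, b = self.pair
        if a == b:
            raise ValueError("swap pair members must be distinct")
        if (a, b) != tuple(sorted((a, b))):
            object.__setattr__(self, "pair", tuple(sorted((a, b))))


def detect_id_switches(
    tracks: TrackSet,
    jump_cm: float = DEFAULT_JUMP_CM,
    refit_cm: float = DEFAULT_REFIT_CM,
) -> list[SwapEvent]:
    """Detect identity switches between pairs of animals.

    A :class:`SwapEvent` is emitted at frame ``f`` for pair ``(A, B)`` when
    A's displacement from ``f-1`` to ``f`` exceeds ``jump_cm`` while B's
    position at ``f`` lies within ``refit_cm`` of A's position at ``f-1``
    (or symmetrically).  Frames separated by recording downtime (timestamp
    gap larger than 1.5 frame steps) are never compared.
    """
    pos = tracks.positions
    names = tracks.animal_names
    if len(names) < 2:
        warnings.warn("single-animal TrackSet: no identity switches possible")
        return []
    disp = np.linalg.norm(pos[1:] - pos[:-1], axis=-1)  # (T-1, A)
    contiguous = np.diff(tracks.timestamps) <= 1.5 / tracks.fps
    jumped = (disp > jump_cm) & contiguous[:, None]
    events: dict[tuple[int, tuple[str, str]], SwapEvent] = {}
    for step, a in zip(*np.nonzero(jumped)):
        f = int(step) + 1
        # other animals whose position at f continues a's old track
        d = np.linalg.norm(pos[f] - pos[f - 1, a], axis=-1)  # (A,)
        d[a] = np.inf
        for b in np.nonzero(d < refit_cm)[0]:
            pair = tuple(sorted((names[a], names[int(b)])))
            events.setdefault((f, pair), SwapEvent(f, pair, "detected"))
    return sorted(events.values(), key=lambda e: (e.frame, e.pair))


def correct_id_switches(
    tracks: TrackSet,
    events: list[SwapEvent],
    scope: str = "to_end",
) -> TrackSet:
    """Undo identity switches by re-exchanging the two tracks.

    With the default ``scope="to_end"`` each event's transposition is applied
    from its frame to the end of the session, processing events newest-first —
    the exact inverse of how segment-level switches compose, so a corrupted
    session is restored even when later switches share an animal with earlier
    ones.  ``scope="next_involving"`` instead swaps only until the next event
    involving either animal.
    """
    out = tracks.copy()
    if not events:
        return out
    T = out.n_frames
    for e in events:
        if not 0 <= e.frame < T:
            raise ValueError(f"event frame {e.frame} outside track range [0, {T})")
    by_frame: dict[int, list[SwapEvent]] = {}
    for e in events:
        by_frame.setdefault(e.frame, []).append(e)
    for f, evs in by_frame.items():
        touched = [n for e in evs for n in e.pair]
        if len(set(touched)) != len(touched):
            raise ValueError(f"contradictory events at frame {f}: {evs}")

    def _swap(a: int, b: int, start: int, stop: int) -> None:
        sl = slice(start, stop)
        out.positions[sl, [a, b]] = out.positions[sl, [b, a]]
        if out.poses is not None:
            out.poses[sl, [a, b]] = out.poses[sl, [b, a]]

    ordered = sorted(events, key=lambda e: (e.frame, e.pair))
    if scope == "to_end":
        for e in reversed(ordered):
            a, b = (out.index_of(n) for n in e.pair)
            _swap(a, b, e.frame, T)
    elif scope == "next_involving":
        for i, e in enumerate(ordered):
            a, b = (out.index_of(n) for n in e.pair)
            stop = T
            for later in ordered[i + 1 :]:
                if set(later.pair) & set(e.pair):
                    stop = later.frame
                    break
            _swap(a, b, e.frame, stop)
    else:
        raise ValueError(f"unknown scope {scope!r}")
    return out


def interpolate_gaps(
    tracks: TrackSet,
    huddles: HuddleTrack | None = None,
    max_gap_cm: float = 3.0,
    max_huddle_gap_s: float = 30.0,
) -> tuple[TrackSet, HuddleTrack | None]:
    """Bridge short track gaps and merge fragmented huddle intervals.

    A missing run for one animal is linearly interpolated iff the Euclidean
    distance between its flanking positions is below ``max_gap_cm`` — short
    enough that the animal cannot have gone far.  Consecutive huddle
    intervals less than ``max_huddle_gap_s`` apart are merged (a huddle at a
    stable nest site that the tracker momentarily lost).
    """
    out = tracks.copy()
    pos = out.positions
    t = out.timestamps
    for a in range(pos.shape[1]):
        missing = np.isnan(pos[:, a, 0])
        if not missing.any() or missing.all():
            continue
        # runs of missing frames with valid flanks
        edges = np.flatnonzero(np.diff(missing.astype(np.int8)))
        starts = edges[missing[edges + 1]] + 1
        ends = edges[~missing[edges + 1]] + 1  # exclusive
        for s in starts:
            e_candidates = ends[ends > s]
            if len(e_candidates) == 0:
                continue  # run extends to session end
            e = e_candidates[0]
            if s == 0:
                continue
            p0, p1 = pos[s - 1, a], pos[e, a]
            if np.linalg.norm(p1 - p0) < max_gap_cm:
                frac = (t[s:e] - t[s - 1]) / (t[e] - t[s - 1])
                pos[s:e, a] = p0 + frac[:, None] * (p1 - p0)
    merged = None
    if huddles is not None and len(huddles):
        iv = huddles.intervals
        keep = [iv[0].copy()]
        for row in iv[1:]:
            prev = keep[-1]
            if row[0] - prev[1] < max_huddle_gap_s:
                w1, w2 = prev[1] - prev[0], row[1] - row[0]
                prev[2:4] = (prev[2:4] * w1 + row[2:4] * w2) / (w1 + w2)
                prev[1] = max(prev[1], row[1])
            else:
                keep.append(row.copy())
        merged = HuddleTrack(np.array(keep))
    elif huddles is not None:
        merged = huddles
    return out, merged


def substitute_day(matrix: DailyBehaviorMatrix, day: int) -> DailyBehaviorMatrix:
    """Replace one day by the mean of its neighbours (cage-cleaning days).

    Bedding changes disturb behavior for a day; the affected day's value is
    replaced per animal by the mean of the flanking days.
    """
    days = matrix.days
    if day - 1 not in days or day + 1 not in days:
        raise ValueError(f"substitute_day({day}) requires days {day - 1} and {day + 1}")
    lo, hi = matrix.values[day - 1], matrix.values[day + 1]
    if lo.isna().any() or hi.isna().any():
        raise ValueError(f"flanking day of {day} has missing values")
    values = matrix.values.copy()
    values[day] = (lo + hi) / 2.0
    return DailyBehaviorMatrix(matrix.behavior, matrix.units, values)


def write_swap_log(events: list[SwapEvent], path) -> None:
    pd.DataFrame(
        [(e.frame, e.pair[0], e.pair[1], e.kind) for e in events],
        columns=["frame", "animal_a", "animal_b", "kind"],
    ).to_csv(path, index=False)


def load_swap_log(path) -> list[SwapEvent]:
    df = pd.read_csv(path)
    return [
        SwapEvent(int(r.frame), (r.animal_a, r.animal_b), r.kind) for r in df.itertuples()
    ]
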