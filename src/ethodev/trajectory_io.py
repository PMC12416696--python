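"""Canonical data model and I/O for multi-animal home-cage trajectory data.

The central container is :class:`TrackSet`: per-frame 2-D positions (cm) for a
named family of gerbils (two adults, up to four pups) recorded continuously
over postnatal days, together with cage geometry, the light schedule and the
per-day recording coverage.  Missing positions are NaN — in this recording
paradigm an animal's open-field track lapses whenever it joins a huddle.

Three on-disk dialects are supported:

* ``canonical-h5`` — the package's own HDF5 layout (lossless round trip).
* ``wide-csv``     — ``time_s, pnd, <animal>_x, <animal>_y`` columns.
* ``pose-export``  — best-effort adapter for pose-tracking HDF5 exports;
  requires an explicit ``px_to_cm`` scale in the file metadata because the
  source calibration is not recoverable from the file itself.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from datetime import datetime, time as dtime, timedelta
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import h5py
import numpy as np
import pandas as pd

__all__ = [
    "AnimalID",
    "BoutSeries",
    "CageGeometry",
    "DailyBehaviorMatrix",
    "FormatError",
    "HuddleTrack",
    "LightSchedule",
    "TrackSet",
    "ValidationError",
    "centroid_series",
    "default_cage",
    "default_family",
    "light_phase",
    "load_bouts",
    "load_daily_matrix",
    "load_trackset",
    "write_bouts",
    "write_daily_matrix",
    "write_trackset",
]

ADULT_NAMES = ("female", "male")
PUP_NAMES = ("pup1", "pup2", "pup3", "pup4")
KNOWN_NAMES = ADULT_NAMES + PUP_NAMES

#: Food-hopper and waterspout ROI sizes in cm (width along x, height along y).
FOOD_HOPPER_SIZE = (19.50, 10.50)
WATERSPOUT_SIZE = (8.50, 8.00)

POSE_NODES = ("nose", "spine1", "spine2", "spine3", "spine4", "spine5")


class FormatError(ValueError):
    """A file does not match its declared on-disk dialect."""


class ValidationError(ValueError):
    """Data violate an invariant of the canonical model."""


@dataclass(frozen=True)
class AnimalID:
    """A named family member; adults are ``female``/``male``, pups ``pup1..4``."""

    name: str
    age_class: str

    def __post_init__(self) -> None:
        if self.name not in KNOWN_NAMES:
            raise ValidationError(
                f"unknown animal name {self.name!r}; expected one of {KNOWN_NAMES}"
            )
        if self.age_class not in ("adult", "pup"):
            raise ValidationError(f"age_class must be 'adult' or 'pup', got {self.age_class!r}")
        expected = "adult" if self.name in ADULT_NAMES else "pup"
        if self.age_class != expected:
            raise ValidationError(f"{self.name} must have age_class {expected!r}")


def default_family(n_pups: int = 4) -> list[AnimalID]:
    """The standard family: 2 adults and ``n_pups`` pups (0-4)."""
    if not 0 <= n_pups <= 4:
        raise ValidationError("a family has at most 4 pups")
    animals = [AnimalID(n, "adult") for n in ADULT_NAMES]
    animals += [AnimalID(n, "pup") for n in PUP_NAMES[:n_pups]]
    return animals


def _validate_family(animals: Sequence[AnimalID]) -> None:
    names = [a.name for a in animals]
    if len(set(names)) != len(names):
        raise ValidationError(f"duplicate animal names: {names}")
    n_adults = sum(a.age_class == "adult" for a in animals)
    n_pups = len(animals) - n_adults
    if n_adults > 2 or n_pups > 4:
        raise ValidationError(
            f"a family has at most 2 adults and 4 pups, got {n_adults} adults, {n_pups} pups"
        )


@dataclass
class CageGeometry:
    """Cage floor rectangle with named rectangular ROIs in cm.

    The origin sits at one cage corner with x along the long (length) axis and
    y along the short (width) axis, so valid coordinates are
    ``[0, length_cm] x [0, width_cm]``.  ROIs are closed rectangles
    ``(x0, y0, x1, y1)``.
    """

    width_cm: float = 35.6
    length_cm: float = 57.2
    rois: dict[str, tuple[float, float, float, float]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.width_cm <= 0 or self.length_cm <= 0:
            raise ValidationError("cage dimensions must be positive")
        for name, (x0, y0, x1, y1) in self.rois.items():
            if not (0 <= x0 < x1 <= self.length_cm and 0 <= y0 < y1 <= self.width_cm):
                raise ValidationError(
                    f"ROI {name!r} = {(x0, y0, x1, y1)} lies outside the "
                    f"{self.length_cm} x {self.width_cm} cm cage"
                )


def default_cage() -> CageGeometry:
    """Cage with food-hopper and waterspout ROIs at their default corners.

    Only the ROI *sizes* are fixed by the recording setup; the corner
    placement is configurable and these defaults put the food hopper along
    one short wall and the waterspout in the opposite far corner.
    """
    fw, fh = FOOD_HOPPER_SIZE
    ww, wh = WATERSPOUT_SIZE
    w, l = 35.6, 57.2
    rois = {
        "food_hopper": (0.0, w - fh, fw, w),
        "waterspout": (l - ww, w - wh, l, w),
    }
    return CageGeometry(width_cm=w, length_cm=l, rois=rois)


def _parse_clock(value: str | dtime) -> dtime:
    if isinstance(value, dtime):
        return value
    h, m = value.split(":")[:2]
    return dtime(int(h), int(m))


@dataclass(frozen=True)
class LightSchedule:
    """Light/dark schedule; day is the half-open interval [day_start, night_start)."""

    day_start: dtime = dtime(8, 0)
    night_start: dtime = dtime(20, 0)

    def __post_init__(self) -> None:
        object.__setattr__(self, "day_start", _parse_clock(self.day_start))
        object.__setattr__(self, "night_start", _parse_clock(self.night_start))
        if self.day_start == self.night_start:
            raise ValidationError("day_start and night_start must differ")


def light_phase(schedule: LightSchedule, wall_clock: dtime | datetime) -> str:
    """Classify a time of day as ``"day"`` or ``"night"`` (half-open convention)."""
    if isinstance(wall_clock, datetime):
        wall_clock = wall_clock.time()
    d, n = schedule.day_start, schedule.night_start
    if d < n:
        return "day" if d <= wall_clock < n else "night"
    # inverted schedule (lights on over midnight)
    return "day" if (wall_clock >= d or wall_clock < n) else "night"


@dataclass
class TrackSet:
    """Time-indexed positions for one family over one or more postnatal days.

    Parameters
    ----------
    fps
        Nominal frame rate; gaps in ``timestamps`` larger than a frame step
        mark recording downtime.
    timestamps
        Seconds since ``anchor`` (strictly increasing), shape ``(T,)``.
    anchor
        Wall-clock datetime of ``t = 0``.
    pnd
        Postnatal-day label per frame, shape ``(T,)`` int.  Day boundaries
        fall at wall-clock midnight.
    animals
        Family members; axis 1 of ``positions`` follows this order.
    positions
        ``(T, A, 2)`` float cm, NaN = missing.
    poses
        Optional ``(T, A, 6, 2)`` six-node skeletons (nose, spine1..spine5).
    coverage
        Mapping postnatal day -> fraction of that day with recording.
    """

    fps: float
    timestamps: np.ndarray
    anchor: datetime
    pnd: np.ndarray
    animals: list[AnimalID]
    positions: np.ndarray
    cage: CageGeometry = field(default_factory=default_cage)
    schedule: LightSchedule = field(default_factory=LightSchedule)
    coverage: dict[int, float] = field(default_factory=dict)
    poses: np.ndarray | None = None
    family_id: str = "family0"

    # -- convenience -------------------------------------------------------
    @property
    def n_frames(self) -> int:
        return len(self.timestamps)

    @property
    def animal_names(self) -> list[str]:
        return [a.name for a in self.animals]

    def index_of(self, animal: str | AnimalID) -> int:
        name = animal.name if isinstance(animal, AnimalID) else animal
        try:
            return self.animal_names.index(name)
        except ValueError:
            raise KeyError(f"animal {name!r} not in TrackSet ({self.animal_names})") from None

    def days(self) -> np.ndarray:
        return np.unique(self.pnd)

    def day_coverage(self, day: int) -> float:
        return float(self.coverage.get(int(day), 1.0))

    def wall_seconds(self) -> np.ndarray:
        """Seconds since midnight of the anchor day, per frame."""
        offset = (
            self.anchor - self.anchor.replace(hour=0, minute=0, second=0, microsecond=0)
        ).total_seconds()
        return self.timestamps + offset

    def copy(self) -> "TrackSet":
        return dataclasses.replace(
            self,
            timestamps=self.timestamps.copy(),
            pnd=self.pnd.copy(),
            positions=self.positions.copy(),
            poses=None if self.poses is None else self.poses.copy(),
            coverage=dict(self.coverage),
        )

    # -- validation --------------------------------------------------------
    def validate(self) -> "TrackSet":
        _validate_family(self.animals)
        t = np.asarray(self.timestamps, dtype=float)
        if t.ndim != 1 or len(t) == 0:
            raise ValidationError("timestamps must be a non-empty 1-D array")
        if np.any(np.diff(t) <= 0):
            bad = int(np.argmax(np.diff(t) <= 0)) + 1
            raise ValidationError(f"timestamps not strictly increasing at frame {bad}")
        if self.fps <= 0:
            raise ValidationError("fps must be positive")
        if self.positions.shape != (len(t), len(self.animals), 2):
            raise ValidationError(
                f"positions shape {self.positions.shape} != "
                f"({len(t)}, {len(self.animals)}, 2)"
            )
        x, y = self.positions[..., 0], self.positions[..., 1]
        eps = 1e-9
        bad = (
            (x < -eps) | (x > self.cage.length_cm + eps) | (y < -eps) | (y > self.cage.width_cm + eps)
        )
        bad &= ~np.isnan(x)
        if bad.any():
            f, a = np.argwhere(bad)[0]
            raise ValidationError(
                f"position out of cage bounds at frame {f}, animal "
                f"{self.animal_names[a]}: {tuple(self.positions[f, a])}"
            )
        for d, c in self.coverage.items():
            if not 0 < c <= 1:
                raise ValidationError(f"coverage for day {d} must be in (0, 1], got {c}")
        return self


@dataclass
class HuddleTrack:
    """Huddle episodes: half-open intervals [start_s, end_s) with a centroid."""

    intervals: np.ndarray  # (N, 4): start_s, end_s, cx, cy
    members: list[frozenset[str]] | None = None

    def __post_init__(self) -> None:
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 4)
        self.intervals = iv[np.argsort(iv[:, 0])] if len(iv) else iv
        if len(iv) and np.any(iv[:, 1] <= iv[:, 0]):
            raise ValidationError("huddle intervals must have end > start")

    def __len__(self) -> int:
        return len(self.intervals)

    def active_mask(self, timestamps: np.ndarray) -> np.ndarray:
        """Boolean per-frame mask: any huddle active at that time."""
        mask = np.zeros(len(timestamps), dtype=bool)
        for s, e, _, _ in self.intervals:
            mask |= (timestamps >= s) & (timestamps < e)
        return mask


@dataclass
class BoutSeries:
    """Sorted, non-overlapping half-open bouts for one behavior and subject."""

    label: str
    subject: str | tuple[str, str]
    bouts: np.ndarray  # (N, 2): start_s, end_s

    def __post_init__(self) -> None:
        b = np.asarray(self.bouts, dtype=float).reshape(-1, 2)
        b = b[np.argsort(b[:, 0])] if len(b) else b
        if len(b) and np.any(b[:, 1] <= b[:, 0]):
            raise ValidationError(f"bouts of {self.label!r} must have end > start")
        if len(b) > 1 and np.any(b[1:, 0] < b[:-1, 1]):
            raise ValidationError(f"bouts of {self.label!r} overlap")
        self.bouts = b

    def __len__(self) -> int:
        return len(self.bouts)

    def total_seconds(self) -> float:
        return float(np.sum(self.bouts[:, 1] - self.bouts[:, 0])) if len(self.bouts) else 0.0


@dataclass
class DailyBehaviorMatrix:
    """Animals x postnatal-days behavior values in absolute units."""

    behavior: str
    units: str
    values: pd.DataFrame  # index = animal names, columns = int postnatal days

    VALID_UNITS = ("hrs/day", "m/day", "count/day", "min/day")

    def __post_init__(self) -> None:
        if self.units not in self.VALID_UNITS:
            raise ValidationError(f"units must be one of {self.VALID_UNITS}, got {self.units!r}")
        self.values = self.values.copy()
        self.values.columns = [int(c) for c in self.values.columns]
        days = list(self.values.columns)
        if days != sorted(days):
            self.values = self.values[sorted(days)]
            days = sorted(days)
        if days and (days != list(range(days[0], days[-1] + 1))):
            raise ValidationError(f"days must be contiguous, got {days}")
        if days and (days[0] < 15 or days[-1] > 30):
            raise ValidationError(f"days must lie within [15, 30], got {days}")
        vals = self.values.to_numpy(dtype=float)
        if np.nanmin(vals, initial=0.0) < -1e-12:
            raise ValidationError(f"{self.behavior}: values must be >= 0")

    @property
    def days(self) -> list[int]:
        return list(self.values.columns)


# ---------------------------------------------------------------------------
# centroids
# ---------------------------------------------------------------------------

def centroid_series(tracks: TrackSet, animal: str | AnimalID) -> np.ndarray:
    """Per-frame (x, y) centroid for one animal, NaN where missing.

    With six-node poses present the centroid is the per-axis **median** over
    available nodes, which damps single-node tracking errors; otherwise the
    stored position passes through unchanged.
    """
    idx = tracks.index_of(animal)
    if tracks.poses is None:
        return tracks.positions[:, idx, :].copy()
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN frames are valid
        med = np.nanmedian(tracks.poses[:, idx, :, :], axis=1)  # (T, 2)
    return med


# ---------------------------------------------------------------------------
# canonical-h5 I/O
# ---------------------------------------------------------------------------

def write_trackset(tracks: TrackSet, path: str | Path) -> None:
    """Write a TrackSet to the canonical HDF5 layout (lossless)."""
    tracks.validate()
    path = Path(path)
    with h5py.File(path, "w") as f:
        meta = f.create_group("meta")
        meta.attrs["fps"] = tracks.fps
        meta.attrs["px_to_cm"] = 1.0
        meta.attrs["width_cm"] = tracks.cage.width_cm
        meta.attrs["length_cm"] = tracks.cage.length_cm
        meta.attrs["day_start"] = tracks.schedule.day_start.strftime("%H:%M")
        meta.attrs["night_start"] = tracks.schedule.night_start.strftime("%H:%M")
        meta.attrs["family_id"] = tracks.family_id
        meta.attrs["anchor"] = tracks.anchor.isoformat()
        if tracks.cage.rois:
            rg = meta.create_group("rois")
            for name, rect in tracks.cage.rois.items():
                rg.create_dataset(name, data=np.asarray(rect, dtype=float), track_times=False)
        cov_days = sorted(tracks.coverage)
        meta.create_dataset("coverage_days", data=np.asarray(cov_days, dtype=np.int64),
                            track_times=False)
        meta.create_dataset(
            "coverage", data=np.asarray([tracks.coverage[d] for d in cov_days], dtype=float),
            track_times=False)
        ag = f.create_group("animals")
        ag.create_dataset(
            "names", data=np.array(tracks.animal_names, dtype="S16"), track_times=False)
        ag.create_dataset(
            "age_class", data=np.array([a.age_class for a in tracks.animals], dtype="S8"),
            track_times=False)
        f.create_dataset("tracks", data=tracks.positions.astype(np.float32),
                         compression="gzip", compression_opts=4, track_times=False)
        if tracks.poses is not None:
            f.create_dataset("poses", data=tracks.poses.astype(np.float32),
                             compression="gzip", compression_opts=4, track_times=False)
        tg = f.create_group("timestamps")
        tg.create_dataset("time_s", data=tracks.timestamps.astype(np.float64),
                          compression="gzip", compression_opts=4, track_times=False)
        tg.create_dataset("pnd", data=tracks.pnd.astype(np.int16),
                          compression="gzip", compression_opts=4, track_times=False)


def _load_canonical_h5(path: Path) -> TrackSet:
    with h5py.File(path, "r") as f:
        for key in ("meta", "animals", "tracks", "timestamps"):
            if key not in f:
                raise FormatError(f"{path}: canonical-h5 file missing group/dataset {key!r}")
        meta = f["meta"]
        names = [n.decode() for n in f["animals/names"][()]]
        classes = [c.decode() for c in f["animals/age_class"][()]]
        animals = [AnimalID(n, c) for n, c in zip(names, classes)]
        rois = {}
        if "rois" in meta:
            for name in meta["rois"]:
                rois[name] = tuple(float(v) for v in meta["rois"][name][()])
        cage = CageGeometry(
            width_cm=float(meta.attrs["width_cm"]),
            length_cm=float(meta.attrs["length_cm"]),
            rois=rois,
        )
        schedule = LightSchedule(str(meta.attrs["day_start"]), str(meta.attrs["night_start"]))
        cov_days = meta["coverage_days"][()]
        cov = {int(d): float(c) for d, c in zip(cov_days, meta["coverage"][()])}
        scale = float(meta.attrs.get("px_to_cm", 1.0))
        ts = TrackSet(
            fps=float(meta.attrs["fps"]),
            timestamps=f["timestamps/time_s"][()].astype(float),
            anchor=datetime.fromisoformat(str(meta.attrs["anchor"])),
            pnd=f["timestamps/pnd"][()].astype(int),
            animals=animals,
            positions=f["tracks"][()].astype(float) * scale,
            poses=f["poses"][()].astype(float) * scale if "poses" in f else None,
            cage=cage,
            schedule=schedule,
            coverage=cov,
            family_id=str(meta.attrs.get("family_id", "family0")),
        )
    return ts.validate()


def _load_wide_csv(path: Path) -> TrackSet:
    df = pd.read_csv(path)
    if "time_s" not in df.columns or "pnd" not in df.columns:
        raise FormatError(f"{path}: wide-csv requires 'time_s' and 'pnd' columns")
    names = []
    for col in df.columns:
        if col.endswith("_x"):
            name = col[:-2]
            if f"{name}_y" not in df.columns:
                raise FormatError(f"{path}: column {col!r} has no matching {name}_y")
            if name not in KNOWN_NAMES:
                raise FormatError(f"{path}: unknown animal column {name!r}")
            names.append(name)
    if not names:
        raise FormatError(f"{path}: no <animal>_x/<animal>_y columns found")
    animals = [AnimalID(n, "adult" if n in ADULT_NAMES else "pup") for n in names]
    t = df["time_s"].to_numpy(dtype=float)
    pos = np.stack(
        [df[[f"{n}_x", f"{n}_y"]].to_numpy(dtype=float) for n in names], axis=1
    )
    dt = np.diff(t)
    fps = 1.0 / np.median(dt) if len(dt) else 25.0
    pnd = df["pnd"].to_numpy(dtype=int)
    anchor = datetime(2000, 1, 1)
    return TrackSet(
        fps=float(fps), timestamps=t, anchor=anchor, pnd=pnd,
        animals=animals, positions=pos,
    ).validate()


def _load_pose_export(path: Path) -> TrackSet:
    """Best-effort adapter for pose-tracking HDF5 exports.

    Expects datasets ``tracks`` with shape (n_animals, 2, n_nodes, n_frames)
    in pixels, ``track_names``, and root attrs ``px_to_cm`` (mandatory — the
    calibration cannot be inferred) and ``fps``.
    """
    with h5py.File(path, "r") as f:
        if "tracks" not in f or "track_names" not in f:
            raise FormatError(f"{path}: pose export missing 'tracks' or 'track_names'")
        if "px_to_cm" not in f.attrs:
            raise FormatError(
                f"{path}: pose export requires a 'px_to_cm' scale attribute; "
                "pixel calibration cannot be inferred from the file"
            )
        scale = float(f.attrs["px_to_cm"])
        fps = float(f.attrs.get("fps", 25.0))
        raw = f["tracks"][()]  # (A, 2, nodes, T) px
        names = [n.decode() if isinstance(n, bytes) else str(n) for n in f["track_names"][()]]
    unknown = [n for n in names if n not in KNOWN_NAMES]
    if unknown:
        raise FormatError(f"{path}: unknown animal track names {unknown}")
    animals = [AnimalID(n, "adult" if n in ADULT_NAMES else "pup") for n in names]
    poses = np.transpose(raw, (3, 0, 2, 1)).astype(float) * scale  # (T, A, nodes, 2)
    with np.errstate(invalid="ignore"):
        positions = np.nanmedian(poses, axis=2)
    T = positions.shape[0]
    t = np.arange(T, dtype=float) / fps
    return TrackSet(
        fps=fps, timestamps=t, anchor=datetime(2000, 1, 1, 0, 0),
        pnd=np.full(T, 15, dtype=int), animals=animals,
        positions=positions, poses=poses if poses.shape[2] == 6 else None,
    ).validate()


_DIALECTS = {
    "canonical-h5": _load_canonical_h5,
    "wide-csv": _load_wide_csv,
    "pose-export": _load_pose_export,
}


def load_trackset(path: str | Path, dialect: str = "canonical-h5") -> TrackSet:
    """Load a TrackSet from disk; see module docstring for the dialects."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    try:
        loader = _DIALECTS[dialect]
    except KeyError:
        raise ValueError(f"unknown dialect {dialect!r}; choose from {sorted(_DIALECTS)}") from None
    return loader(path)


# ---------------------------------------------------------------------------
# bout / matrix CSV I/O
# ---------------------------------------------------------------------------

def _subject_str(subject: str | tuple[str, str]) -> str:
    return "+".join(subject) if isinstance(subject, tuple) else subject


def write_bouts(series: Iterable[BoutSeries], path: str | Path) -> None:
    rows = []
    for s in series:
        for start, end in s.bouts:
            rows.append((s.label, _subject_str(s.subject), start, end))
    pd.DataFrame(rows, columns=["label", "subject", "start_s", "end_s"]).to_csv(
        path, index=False
    )


def load_bouts(path: str | Path) -> list[BoutSeries]:
    df = pd.read_csv(path)
    out = []
    for (label, subj), grp in df.groupby(["label", "subject"], sort=True):
        subject: str | tuple[str, str] = tuple(subj.split("+")) if "+" in subj else subj
        out.append(BoutSeries(label, subject, grp[["start_s", "end_s"]].to_numpy()))
    return out


def write_daily_matrix(matrix: DailyBehaviorMatrix, path: str | Path) -> None:
    long = matrix.values.reset_index(names="animal").melt(
        id_vars="animal", var_name="pnd", value_name="value"
    )
    long.insert(0, "behavior", matrix.behavior)
    long["units"] = matrix.units
    long.sort_values(["animal", "pnd"]).to_csv(path, index=False)


def load_daily_matrix(path: str | Path) -> DailyBehaviorMatrix:
    df = pd.read_csv(path)
    behavior = df["behavior"].iloc[0]
    units = df["units"].iloc[0]
    wide = df.pivot(index="animal", columns="pnd", values="value")
    wide.index.name = None
    wide.columns.name = None
    return DailyBehaviorMatrix(behavior, units, wide)


def write_huddles(huddles: HuddleTrack, path: str | Path) -> None:
    pd.DataFrame(huddles.intervals, columns=["start_s", "end_s", "cx", "cy"]).to_csv(
        path, index=False
    )


def load_huddles(path: str | Path) -> HuddleTrack:
    df = pd.read_csv(path)
    return HuddleTrack(df[["start_s", "end_s", "cx", "cy"]].to_numpy())
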