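"""Developmental-trajectory statistics.

Pup trajectories are expressed relative to the mean of the two adults at the
P29 reference day (adult mean = 1.0).  Rapid-development days are found with
two-sample Kolmogorov-Smirnov tests against the pooled previous two days,
Benjamini-Hochberg adjusted within each behavior.  Inter-behavior similarity
is the Jaccard overlap of convex hulls of per-animal trajectory points in a
shared principal-component space, with the intersection volume estimated by
seeded rejection sampling.  A Monte-Carlo power utility supports cohort-size
planning.
"""
from __future__ import annotations

import warnings
import zlib
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, Delaunay, QhullError
from scipy.stats import ks_2samp, pearsonr, ttest_ind
from sklearn.decomposition import PCA
from statsmodels.stats.multitest import multipletests

from .trajectory_io import DailyBehaviorMatrix

__all__ = [
    "RapidDevelopmentFlags",
    "RelativeTrajectory",
    "hull_overlap",
    "normalize_to_adult",
    "power_at_n",
    "rapid_development_days",
    "shuffle_identity",
    "trajectory_correlations",
]


@dataclass
class RelativeTrajectory:
    """Pup x day values on the adult-relative scale (adult mean at P29 = 1.0)."""

    behavior: str
    values: pd.DataFrame
    reference: float

    def __post_init__(self) -> None:
        if self.reference <= 0:
            raise ValueError(f"{self.behavior}: adult reference must be positive")


@dataclass
class RapidDevelopmentFlags:
    """Days flagged as rapid development, with BH-adjusted p-values per test."""

    behavior: str
    flagged_days: set[int]
    p_adjusted: dict[int, float] = field(default_factory=dict)


def normalize_to_adult(
    matrix: DailyBehaviorMatrix,
    adults: tuple[str, str] = ("female", "male"),
    reference_day: int = 29,
) -> RelativeTrajectory:
    """Express pup values relative to the mean adult value at ``reference_day``."""
    if reference_day not in matrix.days:
        raise ValueError(f"{matrix.behavior}: reference day {reference_day} not present")
    ref_vals = matrix.values.loc[list(adults), reference_day]
    if ref_vals.isna().any():
        raise ValueError(f"{matrix.behavior}: adult value missing at P{reference_day}")
    reference = float(ref_vals.mean())
    if reference == 0:
        raise ValueError(f"{matrix.behavior}: adult reference at P{reference_day} is zero")
    pups = [a for a in matrix.values.index if a not in adults]
    return RelativeTrajectory(matrix.behavior, matrix.values.loc[pups] / reference, reference)


def rapid_development_days(
    values: pd.DataFrame,
    alpha: float = 0.05,
    comparison: str = "previous_only",
) -> RapidDevelopmentFlags:
    """Flag days whose cross-animal distribution differs from neighbouring days.

    For each day ``d`` the animal values at ``d`` are compared by two-sample
    Kolmogorov-Smirnov test with the pooled values of the previous two days
    (and, with ``comparison="both"``, additionally with the following day —
    both tests must then reject).  p-values are Benjamini-Hochberg adjusted
    across all tests within the behavior; a day is flagged when its adjusted
    p-value(s) fall below ``alpha``.  Days with fewer than 3 values in any
    sample are skipped with a warning.
    """
    if comparison not in ("previous_only", "both"):
        raise ValueError(f"comparison must be 'previous_only' or 'both', got {comparison!r}")
    days = sorted(int(c) for c in values.columns)
    tests: list[tuple[int, str, float]] = []  # (day, which, raw p)
    for d in days:
        if d - 2 not in days or d - 1 not in days:
            continue
        if comparison == "both" and d + 1 not in days:
            continue
        cur = values[d].dropna().to_numpy()
        prev = np.concatenate(
            [values[d - 2].dropna().to_numpy(), values[d - 1].dropna().to_numpy()]
        )
        samples = [cur, prev]
        if comparison == "both":
            samples.append(values[d + 1].dropna().to_numpy())
        if any(len(s) < 3 for s in samples):
            warnings.warn(f"day {d}: fewer than 3 values in a comparison sample; skipped")
            continue
        tests.append((d, "prev", ks_2samp(cur, prev).pvalue))
        if comparison == "both":
            tests.append((d, "next", ks_2samp(cur, samples[2]).pvalue))
    if not tests:
        return RapidDevelopmentFlags("", set(), {})
    raw = np.array([p for _, _, p in tests])
    adj = multipletests(raw, alpha=alpha, method="fdr_bh")[1]
    p_by_day: dict[int, float] = {}
    reject: dict[int, bool] = {}
    for (d, _, _), p in zip(tests, adj):
        p_by_day[d] = max(p_by_day.get(d, 0.0), float(p))  # worst test governs
        reject[d] = reject.get(d, True) and (p < alpha)
    flagged = {d for d, r in reject.items() if r}
    return RapidDevelopmentFlags("", flagged, p_by_day)


# ---------------------------------------------------------------------------
# convex-hull overlap
# ---------------------------------------------------------------------------

def _hull_or_none(points: np.ndarray):
    try:
        return Delaunay(points)
    except QhullError:
        return None


def hull_overlap(
    traj_a: pd.DataFrame | np.ndarray,
    traj_b: pd.DataFrame | np.ndarray,
    n_pcs: int = 3,
    n_samples: int = 200_000,
    seed: int = 0,
    denominator: str = "union",
) -> float:
    """Percent overlap of two behaviors' convex hulls in a shared PC space.

    Each row (one animal's multi-day trajectory) becomes one point; a single
    principal-component projection is fitted on the concatenation of both
    matrices so the hulls share one coordinate frame, and the first
    ``n_pcs`` components are kept.  The overlap is
    ``100 * vol(A ∩ B) / vol(A ∪ B)`` (Jaccard; ``denominator="min"`` uses
    the smaller hull instead), with volumes estimated by uniform rejection
    sampling over the joint bounding box.  When either point set cannot form
    a full-dimensional hull the projection falls back to 2 components.
    """
    A = np.asarray(traj_a, dtype=float)
    B = np.asarray(traj_b, dtype=float)
    if len(A) < 3 or len(B) < 3:
        raise ValueError("hull_overlap needs at least 3 points per behavior")
    stacked = np.vstack([A, B])
    k = min(n_pcs, stacked.shape[1], len(stacked) - 1)
    pca = PCA(n_components=k, random_state=0)
    proj = pca.fit_transform(stacked)
    for dim in (k, 2):
        pa, pb = proj[: len(A), :dim], proj[len(A) :, :dim]
        ha, hb = _hull_or_none(pa), _hull_or_none(pb)
        if ha is not None and hb is not None:
            break
    else:
        raise ValueError("point sets are degenerate even in 2 components")
    lo = np.minimum(pa.min(axis=0), pb.min(axis=0))
    hi = np.maximum(pa.max(axis=0), pb.max(axis=0))
    rng = np.random.default_rng(seed)
    pts = rng.uniform(lo, hi, size=(n_samples, pa.shape[1]))
    in_a = ha.find_simplex(pts) >= 0
    in_b = hb.find_simplex(pts) >= 0
    inter = np.count_nonzero(in_a & in_b)
    if denominator == "union":
        denom = np.count_nonzero(in_a | in_b)
    elif denominator == "min":
        denom = min(np.count_nonzero(in_a), np.count_nonzero(in_b))
    else:
        raise ValueError(f"unknown denominator {denominator!r}")
    return 100.0 * inter / denom if denom else 0.0


def shuffle_identity(
    values: pd.DataFrame | np.ndarray, seed: int
) -> pd.DataFrame | np.ndarray:
    """Permute animal labels independently on each day (destroys cross-day identity)."""
    arr = np.asarray(values, dtype=float)
    if arr.shape[0] < 2:
        raise ValueError("shuffle_identity needs at least 2 animals")
    rng = np.random.default_rng(seed)
    out = arr.copy()
    for j in range(arr.shape[1]):
        out[:, j] = out[rng.permutation(arr.shape[0]), j]
    if isinstance(values, pd.DataFrame):
        return pd.DataFrame(out, index=values.index, columns=values.columns)
    return out


def trajectory_correlations(
    matrices: dict[str, pd.DataFrame], shuffled_seed: int | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlations between individual animal trajectories.

    For every pair of (behavior, animal) trajectories over the shared day
    axis, returns a long table with columns ``behavior_a, behavior_b,
    animal_a, animal_b, scope, r`` where scope is ``within``/``between``
    behavior.  With ``shuffled_seed`` set, correlations are computed on
    identity-shuffled copies instead.  Zero-variance trajectories are
    excluded with a warning.
    """
    items = []
    for beh, df in matrices.items():
        vals = df if shuffled_seed is None else shuffle_identity(
            df, seed=shuffled_seed + zlib.crc32(beh.encode()) % 10_000
        )
        for animal in vals.index:
            v = vals.loc[animal].to_numpy(dtype=float)
            if np.nanstd(v) == 0:
                warnings.warn(f"{beh}/{animal}: zero-variance trajectory excluded")
                continue
            items.append((beh, animal, v))
    rows = []
    for (b1, a1, v1), (b2, a2, v2) in combinations(items, 2):
        ok = ~np.isnan(v1) & ~np.isnan(v2)
        if ok.sum() < 3:
            continue
        r = pearsonr(v1[ok], v2[ok]).statistic
        scope = "within" if b1 == b2 else "between"
        rows.append((b1, b2, a1, a2, scope, r))
    return pd.DataFrame(
        rows, columns=["behavior_a", "behavior_b", "animal_a", "animal_b", "scope", "r"]
    )


def power_at_n(
    n_per_group: int,
    mean_a: float,
    sd_a: float,
    mean_b: float,
    sd_b: float,
    alpha: float = 0.05,
    reps: int = 10_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo power of a two-sided Welch two-sample test.

    Draws ``reps`` replicate experiments of ``n_per_group`` normal values per
    group and returns the fraction rejecting at level ``alpha``.
    """
    if sd_a <= 0 or sd_b <= 0:
        raise ValueError("standard deviations must be positive")
    if reps < 1000:
        raise ValueError("use at least 1000 replicates for a stable estimate")
    rng = np.random.default_rng(seed)
    xa = rng.normal(mean_a, sd_a, size=(reps, n_per_group))
    xb = rng.normal(mean_b, sd_b, size=(reps, n_per_group))
    p = ttest_ind(xa, xb, axis=1, equal_var=False).pvalue
    return float(np.mean(p < alpha))
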