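"""Shared builders for scripted track fixtures (all data generated in-test)."""
from __future__ import annotations

from datetime import datetime

import numpy as np
import pytest

from ethodev.trajectory_io import (
    AnimalID,
    TrackSet,
    default_cage,
    default_family,
)

ADULTS = [AnimalID("female", "adult"), AnimalID("male", "adult")]


def scripted_trackset(
    positions: np.ndarray,
    fps: float = 25.0,
    animals: list[AnimalID] | None = None,
    poses: np.ndarray | None = None,
    pnd_day: int = 15,
) -> TrackSet:
    """TrackSet from an explicit (T, A, 2) position array, anchored at midnight."""
    positions = np.asarray(positions, dtype=float)
    T, A = positions.shape[:2]
    if animals is None:
        animals = default_family(max(A - 2, 0))[:A]
    return TrackSet(
        fps=fps,
        timestamps=np.arange(T, dtype=float) / fps,
        anchor=datetime(2023, 1, 1),
        pnd=np.full(T, pnd_day, dtype=int),
        animals=animals,
        positions=positions,
        poses=poses,
        cage=default_cage(),
        coverage={pnd_day: 1.0},
    ).validate()


@pytest.fixture
def two_animal_tracks() -> TrackSet:
    """Two parallel, never-crossing tracks of 100 frames."""
    T = 100
    pos = np.empty((T, 2, 2))
    pos[:, 0] = np.column_stack([np.linspace(5, 25, T), np.full(T, 10.0)])
    pos[:, 1] = np.column_stack([np.linspace(5, 25, T), np.full(T, 25.0)])
    return scripted_trackset(pos, animals=ADULTS)
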