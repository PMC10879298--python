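from __future__ import annotations

import numpy as np
import pytest

from macrotraj import (
    ClassLabel,
    SimConfig,
    TrackPoint,
    TrackSet,
    Trajectory,
    generate_labeled_dataset,
)


def make_trajectory(
    xy, cell_id: str = "cell", label: ClassLabel | None = None,
    frame_interval: float = 5.0,
) -> Trajectory:
    """Build a trajectory from an (n, 2) coordinate array."""
    pts = [
        TrackPoint(k, k * frame_interval, float(x), float(y))
        for k, (x, y) in enumerate(np.asarray(xy, dtype=float))
    ]
    return Trajectory(cell_id, pts, label)


def random_trajectory(
    rng: np.random.Generator, n: int = 37, label: ClassLabel | None = None,
    cell_id: str = "cell",
) -> Trajectory:
    return make_trajectory(rng.normal(0, 10, size=(n, 2)), cell_id, label)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


@pytest.fixture
def small_labeled_trackset(rng) -> TrackSet:
    """Nine random labeled complete tracks, three per class."""
    labels = [ClassLabel.M0, ClassLabel.M1, ClassLabel.M2]
    trajs = [
        random_trajectory(rng, n=37, label=lab, cell_id=f"{lab.value}_{i}")
        for lab in labels
        for i in range(3)
    ]
    return TrackSet(trajs, frame_interval=5.0, n_frames=37)


@pytest.fixture(scope="session")
def default_benchmark() -> TrackSet:
    """The shipped synthetic culture at 100 cells per class, seed 0."""
    return generate_labeled_dataset(SimConfig(n_per_class=100, seed=0))
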