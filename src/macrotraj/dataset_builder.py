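"""Feature construction and train/validation splitting.

Each complete trajectory becomes one fixed-length feature vector
``[x_0..x_{T-1}, y_0..y_{T-1}, path_length, net_displacement]`` of
length ``2*T + 2`` (76 for the default 37-frame tracks), with a one-hot
label over (M0, M1, M2). Coordinates are centered on the start point by
default, making the features translation-invariant and letting the
origin-based symmetry augmentations act about each cell's own starting
position; raw image coordinates are available via the flag.

The split shuffles records with a seeded generator (after sorting by
cell id, so the partition does not depend on input order) and takes
``floor(train_fraction * N)`` for training — 448/112 at N = 560.

Note that splitting happens after augmentation: the 8 symmetry variants
of one original cell may land on both sides of the split, so validation
scores are optimistic about truly unseen cells. ``group_by_origin``
keeps all variants of a cell together, at the cost of inexact split
sizes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import traj_metrics
from .track_io import ClassLabel, LabelError, TrackSet, Trajectory

__all__ = [
    "FeatureRecord",
    "SplitResult",
    "ShapeError",
    "build_feature_vector",
    "build_dataset",
    "one_hot",
    "shuffle_split",
    "feature_length",
]


class ShapeError(ValueError):
    """A record's shape or length does not match the dataset contract."""


@dataclass
class FeatureRecord:
    """One classifier input row: features plus (optionally) a one-hot label."""

    cell_id: str
    features: np.ndarray
    label: ClassLabel | None = None

    @property
    def onehot(self) -> np.ndarray:
        if self.label is None:
            raise LabelError(f"record {self.cell_id!r} has no label")
        return one_hot(self.label)


@dataclass
class SplitResult:
    train: list[FeatureRecord]
    validation: list[FeatureRecord]
    seed: int


def feature_length(n_frames: int) -> int:
    """Length of the feature vector for tracks of ``n_frames`` points."""
    return 2 * n_frames + 2


def one_hot(label: ClassLabel) -> np.ndarray:
    """Encode a class label as a 3-vector, order fixed (M0, M1, M2)."""
    label = ClassLabel.parse(label)
    v = np.zeros(3)
    v[label.index] = 1.0
    return v


def build_feature_vector(
    traj: Trajectory,
    n_frames: int,
    center_on_start: bool = True,
    standardize: bool = False,
) -> FeatureRecord:
    """Flatten one complete trajectory into a feature record.

    Layout: all x coordinates, then all y, then the distance traveled
    and the net displacement (both translation-invariant, so unaffected
    by centering). ``standardize`` z-scores the vector in-place
    (mean 0, sd 1 over its own entries) — off by default.
    """
    if len(traj) != n_frames:
        raise ShapeError(
            f"cell {traj.cell_id!r}: expected {n_frames} frames, "
            f"observed {len(traj)}"
        )
    xy = traj.xy
    if center_on_start:
        xy = xy - xy[0]
    features = np.concatenate(
        [
            xy[:, 0],
            xy[:, 1],
            [traj_metrics.path_length(xy), traj_metrics.net_displacement(xy)],
        ]
    )
    if standardize:
        sd = features.std()
        features = (features - features.mean()) / (sd if sd > 0 else 1.0)
    return FeatureRecord(traj.cell_id, features, traj.label)


def build_dataset(
    tracks: TrackSet,
    center_on_start: bool = True,
    standardize: bool = False,
    require_labels: bool = False,
) -> list[FeatureRecord]:
    """Feature records for every trajectory of a TrackSet, in order."""
    if tracks.n_frames is None:
        raise ShapeError("TrackSet.n_frames must be set to build features")
    if require_labels:
        missing = [t.cell_id for t in tracks if t.label is None]
        if missing:
            raise LabelError(f"unlabeled trajectories: {missing[:5]}")
    return [
        build_feature_vector(t, tracks.n_frames, center_on_start, standardize)
        for t in tracks
    ]


def shuffle_split(
    records: list[FeatureRecord],
    train_fraction: float = 0.8,
    seed: int = 0,
    group_by_origin: bool = False,
) -> SplitResult:
    """Seeded shuffled partition into train and validation sets.

    Records are sorted by cell id before shuffling so the result is
    independent of input order. Training takes the first
    ``floor(train_fraction * N)`` after the permutation; the rest is
    validation. With ``group_by_origin`` the shuffle acts on origin
    cells (ids up to the ``__<op>`` suffix) and whole groups are
    assigned to one side, so no augmented variant of a validation cell
    is ever trained on.
    """
    if not 0.0 < train_fraction < 1.0:
        raise ValueError(f"train_fraction must be in (0,1), got {train_fraction}")
    if len(records) < 2:
        raise ValueError("need at least 2 records to split")
    rng = np.random.default_rng(seed)
    ordered = sorted(records, key=lambda r: r.cell_id)
    if group_by_origin:
        groups: dict[str, list[FeatureRecord]] = {}
        for r in ordered:
            groups.setdefault(r.cell_id.split("__")[0], []).append(r)
        keys = sorted(groups)
        perm = [keys[i] for i in rng.permutation(len(keys))]
        n_train_groups = int(np.floor(train_fraction * len(keys)))
        train = [r for k in perm[:n_train_groups] for r in groups[k]]
        validation = [r for k in perm[n_train_groups:] for r in groups[k]]
    else:
        perm = [ordered[i] for i in rng.permutation(len(ordered))]
        n_train = int(np.floor(train_fraction * len(perm)))
        train, validation = perm[:n_train], perm[n_train:]
    return SplitResult(train, validation, seed)
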