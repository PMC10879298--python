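"""Reading, validating and writing single-cell track tables.

Tracks are exchanged as UTF-8 CSV with a header row and columns
``cell_id, frame, t, x, y, label`` (``t`` and ``label`` optional).
Frames are 0-based; when the time column is absent it is derived as
``frame * frame_interval``. Coordinates are stored as received — the
unit tag on :class:`TrackSet` is metadata only, no conversion is done.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "ClassLabel",
    "TrackPoint",
    "Trajectory",
    "TrackSet",
    "TrackFormatError",
    "TrackValidationError",
    "ConfigurationError",
    "LabelError",
    "read_tracks",
    "write_tracks",
    "filter_complete_tracks",
]


class TrackFormatError(ValueError):
    """The file does not follow the expected tabular schema."""


class TrackValidationError(ValueError):
    """The table parsed but violates a track invariant."""


class ConfigurationError(ValueError):
    """A required configuration field is unset or inconsistent."""


class LabelError(ValueError):
    """A class label is missing or not recognised."""


class ClassLabel(enum.Enum):
    """Macrophage polarization state.

    M0 is the naive state, M1 the classically (pro-inflammatory) and M2
    the alternatively (pro-reparatory) activated state.  Morphology
    cluster names map onto them one-to-one: circular cells (Cluster C)
    stand for M0, protruded cells (Cluster P) for M1 and elongated cells
    (Cluster E) for M2.
    """

    M0 = "M0"
    M1 = "M1"
    M2 = "M2"

    @property
    def cluster_name(self) -> str:
        return _LABEL_TO_CLUSTER[self]

    @property
    def index(self) -> int:
        """Fixed class index: M0=0, M1=1, M2=2."""
        return _LABEL_ORDER.index(self)

    @classmethod
    def parse(cls, value: "ClassLabel | str") -> "ClassLabel":
        """Parse a label or one of its morphology-cluster aliases."""
        if isinstance(value, cls):
            return value
        key = str(value).strip()
        try:
            return _ALIASES[key.upper()]
        except KeyError:
            raise LabelError(
                f"unknown class label {value!r}; expected one of "
                f"M0/M1/M2 or Cluster C/P/E"
            ) from None


_LABEL_ORDER = (ClassLabel.M0, ClassLabel.M1, ClassLabel.M2)
_LABEL_TO_CLUSTER = {
    ClassLabel.M0: "Cluster C",
    ClassLabel.M1: "Cluster P",
    ClassLabel.M2: "Cluster E",
}
_ALIASES = {
    "M0": ClassLabel.M0,
    "M1": ClassLabel.M1,
    "M2": ClassLabel.M2,
    "CLUSTER C": ClassLabel.M0,
    "CLUSTER P": ClassLabel.M1,
    "CLUSTER E": ClassLabel.M2,
    "C": ClassLabel.M0,
    "P": ClassLabel.M1,
    "E": ClassLabel.M2,
}


@dataclass(frozen=True)
class TrackPoint:
    """One sampled centroid position: frame index, time (min), x, y."""

    frame: int
    t: float
    x: float
    y: float


@dataclass
class Trajectory:
    """Ordered centroid samples of one tracked cell.

    Points must be strictly increasing in frame with no duplicates.
    """

    cell_id: str
    points: list[TrackPoint]
    label: ClassLabel | None = None

    def __post_init__(self) -> None:
        frames = [p.frame for p in self.points]
        if any(b <= a for a, b in zip(frames, frames[1:])):
            raise TrackValidationError(
                f"cell {self.cell_id!r}: frames must be strictly increasing "
                f"with no duplicates"
            )

    def __len__(self) -> int:
        return len(self.points)

    @property
    def frames(self) -> np.ndarray:
        return np.array([p.frame for p in self.points], dtype=int)

    @property
    def times(self) -> np.ndarray:
        return np.array([p.t for p in self.points], dtype=float)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of coordinates in point order."""
        return np.array([(p.x, p.y) for p in self.points], dtype=float)

    def with_xy(self, xy: np.ndarray, cell_id: str | None = None) -> "Trajectory":
        """Copy of this trajectory with coordinates replaced, times kept."""
        xy = np.asarray(xy, dtype=float)
        if xy.shape != (len(self.points), 2):
            raise TrackValidationError(
                f"cell {self.cell_id!r}: replacement coordinates have shape "
                f"{xy.shape}, expected {(len(self.points), 2)}"
            )
        pts = [
            TrackPoint(p.frame, p.t, float(x), float(y))
            for p, (x, y) in zip(self.points, xy)
        ]
        return Trajectory(cell_id or self.cell_id, pts, self.label)


@dataclass
class TrackSet:
    """A collection of trajectories sharing a recording geometry.

    ``frame_interval`` is minutes per frame; ``n_frames`` the expected
    number of frames of a complete track (default 37 frames at 5 min,
    i.e. a 180 min recording).
    """

    trajectories: list[Trajectory] = field(default_factory=list)
    frame_interval: float = 5.0
    n_frames: int | None = 37
    units: str = "px"

    def __post_init__(self) -> None:
        ids = [t.cell_id for t in self.trajectories]
        if len(set(ids)) != len(ids):
            dup = sorted({i for i in ids if ids.count(i) > 1})
            raise TrackValidationError(f"duplicate cell_ids in TrackSet: {dup}")

    def __len__(self) -> int:
        return len(self.trajectories)

    def __iter__(self):
        return iter(self.trajectories)

    @property
    def labels(self) -> list[ClassLabel | None]:
        return [t.label for t in self.trajectories]


_REQUIRED_COLUMNS = ("cell_id", "frame", "x", "y")


def read_tracks(
    path,
    frame_interval: float = 5.0,
    n_frames: int | None = 37,
    units: str = "px",
    column_map: dict[str, str] | None = None,
) -> TrackSet:
    """Read a track table from CSV.

    Parameters
    ----------
    path
        CSV file with header columns ``cell_id, frame, x, y`` and
        optionally ``t`` and ``label``.
    frame_interval
        Minutes per frame; used to derive ``t`` when absent.
    n_frames
        Expected frames of a complete track (carried on the TrackSet).
    column_map
        Optional mapping from the file's column names to the canonical
        ones, for ingesting tracking-tool exports (e.g.
        ``{"TRACK_ID": "cell_id", "POSITION_X": "x", ...}``).
    """
    df = pd.read_csv(path, dtype={0: str}, float_precision="round_trip")
    if column_map:
        df = df.rename(columns=column_map)
    for col in _REQUIRED_COLUMNS:
        if col not in df.columns:
            raise TrackFormatError(f"missing required column {col!r}")
    df["cell_id"] = df["cell_id"].astype(str)

    for col in ("frame", "x", "y") + (("t",) if "t" in df.columns else ()):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna() & df[col].notna()
        if bad.any():
            row = int(bad.idxmax()) + 2  # 1-based, plus header row
            raise TrackValidationError(
                f"non-numeric value {df[col][bad.idxmax()]!r} in column "
                f"{col!r} at file row {row}"
            )
        if numeric.isna().any():
            row = int(numeric.isna().idxmax()) + 2
            raise TrackValidationError(
                f"missing value in column {col!r} at file row {row}"
            )
        df[col] = numeric

    dup = df.duplicated(subset=["cell_id", "frame"])
    if dup.any():
        first = df.loc[dup.idxmax()]
        raise TrackValidationError(
            f"duplicate (cell_id, frame) = ({first['cell_id']!r}, "
            f"{int(first['frame'])})"
        )

    has_t = "t" in df.columns
    has_label = "label" in df.columns

    trajectories = []
    for cell_id, group in df.groupby("cell_id", sort=False):
        group = group.sort_values("frame")
        label = None
        if has_label:
            raw = group["label"].dropna().unique()
            if len(raw) > 1:
                raise TrackValidationError(
                    f"cell {cell_id!r} carries conflicting labels: {list(raw)}"
                )
            if len(raw) == 1:
                label = ClassLabel.parse(raw[0])
        points = [
            TrackPoint(
                frame=int(r.frame),
                t=float(r.t) if has_t else int(r.frame) * frame_interval,
                x=float(r.x),
                y=float(r.y),
            )
            for r in group.itertuples()
        ]
        trajectories.append(Trajectory(str(cell_id), points, label))

    return TrackSet(trajectories, frame_interval, n_frames, units)


def write_tracks(tracks: TrackSet, path) -> str:
    """Write a TrackSet to CSV; round-trips through :func:`read_tracks`.

    Coordinates are written with ``repr`` precision so the round trip is
    exact. A label column is emitted whenever any trajectory is labeled.
    """
    rows = []
    any_label = any(t.label is not None for t in tracks)
    for traj in tracks:
        for p in traj.points:
            row = {
                "cell_id": traj.cell_id,
                "frame": p.frame,
                "t": p.t,
                "x": p.x,
                "y": p.y,
            }
            if any_label:
                row["label"] = traj.label.value if traj.label else ""
            rows.append(row)
    columns = ["cell_id", "frame", "t", "x", "y"] + (["label"] if any_label else [])
    # default float formatting is the shortest round-trippable repr
    pd.DataFrame(rows, columns=columns).to_csv(path, index=False)
    return str(path)


def filter_complete_tracks(tracks: TrackSet) -> TrackSet:
    """Keep only cells tracked from the first to the last frame.

    A complete track has frames exactly {0, ..., n_frames - 1} with no
    gaps; anything starting late, ending early or skipping frames is
    dropped. Input order is preserved, and the operation is idempotent.
    """
    if tracks.n_frames is None:
        raise ConfigurationError("TrackSet.n_frames must be set to filter")
    want = np.arange(tracks.n_frames)
    kept = [
        t
        for t in tracks
        if len(t) == tracks.n_frames and np.array_equal(t.frames, want)
    ]
    return replace(tracks, trajectories=kept)
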