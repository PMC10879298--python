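"""Symmetry-based trajectory augmentation.

The labeled track set is expanded by the eight axis symmetries of the
plane (the dihedral group of the coordinate axes): the identity, the
coordinate swap, and the six sign-flip / swap-and-flip combinations.
All eight maps are isometries, so every trajectory metric — path
length, displacement, hull perimeter and area, maximum pairwise
distance — is exactly preserved, while the coordinate time series fed
to the classifier changes. Applied about the origin, which coincides
with each cell's own start point once features are centered on the
start.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .track_io import LabelError, TrackSet, Trajectory

__all__ = ["SymmetryOp", "SYMMETRY_OPS", "apply_symmetry", "augment_trackset"]


@dataclass(frozen=True)
class SymmetryOp:
    """A named linear isometry (x, y) -> (a·x|y, b·x|y) of the plane."""

    name: str
    matrix: tuple[tuple[int, int], tuple[int, int]]

    def apply(self, xy: np.ndarray) -> np.ndarray:
        return np.asarray(xy, dtype=float) @ np.asarray(self.matrix, dtype=float).T


# fixed order: identity first, then the seven proper transforms
SYMMETRY_OPS: tuple[SymmetryOp, ...] = (
    SymmetryOp("identity", ((1, 0), (0, 1))),        # (x, y)
    SymmetryOp("swap", ((0, 1), (1, 0))),            # (y, x)
    SymmetryOp("neg_x", ((-1, 0), (0, 1))),          # (-x, y)
    SymmetryOp("neg_both", ((-1, 0), (0, -1))),      # (-x, -y)
    SymmetryOp("neg_y", ((1, 0), (0, -1))),          # (x, -y)
    SymmetryOp("swap_neg_x", ((0, -1), (1, 0))),     # (-y, x)
    SymmetryOp("swap_neg_both", ((0, -1), (-1, 0))), # (-y, -x)
    SymmetryOp("swap_neg_y", ((0, 1), (-1, 0))),     # (y, -x)
)

_OPS_BY_NAME = {op.name: op for op in SYMMETRY_OPS}


def get_op(name: str) -> SymmetryOp:
    try:
        return _OPS_BY_NAME[name]
    except KeyError:
        raise KeyError(
            f"unknown symmetry op {name!r}; choose from "
            f"{[op.name for op in SYMMETRY_OPS]}"
        ) from None


def apply_symmetry(traj: Trajectory, op: SymmetryOp) -> Trajectory:
    """Transform a trajectory's coordinates by one symmetry op.

    Frames, times and label are untouched; the cell id gains the op
    name as a suffix so augmented records never collide with originals.
    """
    return traj.with_xy(op.apply(traj.xy), cell_id=f"{traj.cell_id}__{op.name}")


def augment_trackset(tracks: TrackSet, include_identity: bool = True) -> TrackSet:
    """Expand every labeled cell by the 8 symmetry variants.

    With ``include_identity`` (default) each input cell yields 8
    records (the suffixed original plus 7 transforms); without it, 7.
    Ordering is deterministic: input cell order, then the fixed op
    order. Unlabeled trajectories are rejected — augmentation exists to
    enlarge training data, which must be labeled.
    """
    unlabeled = [t.cell_id for t in tracks if t.label is None]
    if unlabeled:
        raise LabelError(
            f"cannot augment unlabeled trajectories: {unlabeled[:5]}"
            f"{'...' if len(unlabeled) > 5 else ''}"
        )
    ops = SYMMETRY_OPS if include_identity else SYMMETRY_OPS[1:]
    out = [apply_symmetry(t, op) for t in tracks for op in ops]
    return replace(tracks, trajectories=out)
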