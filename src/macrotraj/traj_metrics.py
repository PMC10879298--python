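"""Quantitative trajectory measures.

Five scalar summaries of a planar cell track: path length (total
distance traveled), net displacement (start-to-end distance), convex
hull perimeter and area (the territory the track covers), and maximum
pairwise distance (the diameter of the point set). All are computed on
the full set of trajectory points, start point included.

Degenerate hulls follow the flattened-polygon limit: a 2-vertex hull
has perimeter twice the segment length and zero area; a 1-vertex hull
has perimeter and area zero. This keeps ``perimeter >= 2 * diameter``
true for every hull, with equality in the collinear case.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from scipy.spatial.distance import pdist

from .track_io import TrackSet, Trajectory

__all__ = [
    "MetricInputError",
    "path_length",
    "net_displacement",
    "convex_hull",
    "hull_perimeter_area",
    "max_pairwise_distance",
    "trajectory_metrics",
    "summarize_metrics",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = (
    "cell_id",
    "path_length",
    "net_displacement",
    "hull_perimeter",
    "hull_area",
    "max_pairwise_distance",
)


class MetricInputError(ValueError):
    """The input does not admit the requested metric."""


def _as_points(obj) -> np.ndarray:
    if isinstance(obj, Trajectory):
        return obj.xy
    pts = np.asarray(obj, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise MetricInputError(f"expected (n, 2) points, got shape {pts.shape}")
    return pts


def path_length(traj) -> float:
    """Total distance traveled: sum of consecutive point-to-point distances."""
    pts = _as_points(traj)
    if len(pts) < 2:
        raise MetricInputError("path_length needs at least 2 points")
    return float(np.linalg.norm(np.diff(pts, axis=0), axis=1).sum())


def net_displacement(traj) -> float:
    """Euclidean distance between the first and last trajectory points."""
    pts = _as_points(traj)
    if len(pts) < 2:
        raise MetricInputError("net_displacement needs at least 2 points")
    return float(np.linalg.norm(pts[-1] - pts[0]))


def convex_hull(points) -> np.ndarray:
    """Vertices of the convex hull, counter-clockwise, strict.

    Strict means no interior points and no points lying on a hull edge
    between two vertices; the vertex set is then unique. Degenerate
    inputs: all points coincident -> that single point; all points
    collinear -> the two extreme points.
    """
    pts = _as_points(points)
    if len(pts) == 0:
        raise MetricInputError("convex_hull needs at least 1 point")
    uniq = np.unique(pts, axis=0)
    if len(uniq) == 1:
        return uniq
    try:
        hull = ConvexHull(uniq)
    except QhullError:
        # collinear: project on the principal direction, take the extremes
        d = uniq - uniq.mean(axis=0)
        direction = d[np.argmax(np.linalg.norm(d, axis=1))]
        proj = d @ direction
        return np.array([uniq[np.argmin(proj)], uniq[np.argmax(proj)]])
    verts = uniq[hull.vertices]  # scipy returns CCW order in 2-D
    return _drop_collinear(verts)


def _drop_collinear(verts: np.ndarray, tol: float = 1e-12) -> np.ndarray:
    """Remove vertices lying on the segment between their neighbours."""
    if len(verts) <= 2:
        return verts
    scale = max(np.abs(verts).max(), 1.0)
    keep = []
    n = len(verts)
    for i in range(n):
        a, b, c = verts[i - 1], verts[i], verts[(i + 1) % n]
        cross = (b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0])
        if abs(cross) > tol * scale * scale:
            keep.append(i)
    return verts[keep] if keep else verts[:2]


def hull_perimeter_area(hull: np.ndarray) -> tuple[float, float]:
    """Perimeter and shoelace area of an ordered convex polygon.

    2-vertex hulls count the segment twice (out and back) with zero
    area; 1-vertex hulls are (0, 0).
    """
    hull = np.asarray(hull, dtype=float)
    if len(hull) == 1:
        return 0.0, 0.0
    if len(hull) == 2:
        return 2.0 * float(np.linalg.norm(hull[1] - hull[0])), 0.0
    closed = np.vstack([hull, hull[0]])
    edges = np.diff(closed, axis=0)
    perimeter = float(np.linalg.norm(edges, axis=1).sum())
    x, y = hull[:, 0], hull[:, 1]
    area = 0.5 * abs(float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))))
    return perimeter, area


def max_pairwise_distance(points) -> float:
    """Diameter of the point set: largest distance over all point pairs."""
    pts = _as_points(points)
    if len(pts) < 2:
        raise MetricInputError("max_pairwise_distance needs at least 2 points")
    return float(pdist(pts).max())


def trajectory_metrics(traj: Trajectory) -> dict[str, float]:
    """All five metrics of one trajectory, keyed as in METRIC_COLUMNS."""
    pts = _as_points(traj)
    if len(pts) < 2:
        raise MetricInputError(
            f"cell {getattr(traj, 'cell_id', '?')!r}: metrics need >= 2 points"
        )
    perimeter, area = hull_perimeter_area(convex_hull(pts))
    return {
        "path_length": path_length(pts),
        "net_displacement": net_displacement(pts),
        "hull_perimeter": perimeter,
        "hull_area": area,
        "max_pairwise_distance": max_pairwise_distance(pts),
    }


def summarize_metrics(tracks: TrackSet) -> pd.DataFrame:
    """One metrics row per cell, in TrackSet order, plus the label if set."""
    rows = []
    for traj in tracks:
        try:
            m = trajectory_metrics(traj)
        except MetricInputError as exc:
            raise MetricInputError(f"cell {traj.cell_id!r}: {exc}") from exc
        row = {"cell_id": traj.cell_id, **m}
        row["label"] = traj.label.value if traj.label is not None else None
        rows.append(row)
    return pd.DataFrame(rows, columns=list(METRIC_COLUMNS) + ["label"])
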