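"""Independent brute-force oracles used to validate the geometry code.

These deliberately avoid scipy.spatial (which backs the implementation)
so hull and diameter results are cross-checked by a second route.
"""

from __future__ import annotations

import math

import numpy as np


def brute_hull_vertex_set(points: np.ndarray) -> set[tuple[float, float]]:
    """Strict convex-hull vertices by the O(n^3) edge test.

    (i, j) is a hull edge iff every other point lies strictly to the
    left of the directed line i -> j; vertices are edge endpoints.
    Assumes generic position (no duplicate points, no collinear
    triples), which holds for random float coordinates.
    """
    pts = np.asarray(points, dtype=float)
    n = len(pts)
    vertices: set[int] = set()
    for i in range(n):
        diff = pts - pts[i]
        # cross[j, k] = (p_j - p_i) x (p_k - p_i)
        cross = np.outer(diff[:, 0], diff[:, 1]) - np.outer(diff[:, 1], diff[:, 0])
        mask = ~np.eye(n, dtype=bool)
        mask[:, i] = False
        left_of_all = np.where(mask, cross > 0, True).all(axis=1)
        left_of_all[i] = False
        for j in np.flatnonzero(left_of_all):
            vertices.add(i)
            vertices.add(int(j))
    return {tuple(pts[v]) for v in vertices}


def brute_max_pairwise(points) -> float:
    """Diameter by the O(n^2) double loop, pure python."""
    pts = [tuple(p) for p in np.asarray(points, dtype=float)]
    best = 0.0
    for a in range(len(pts)):
        ax, ay = pts[a]
        for b in range(a + 1, len(pts)):
            bx, by = pts[b]
            d = math.sqrt((ax - bx) ** 2 + (ay - by) ** 2)
            if d > best:
                best = d
    return best


def polygon_perimeter_area_oracle(verts: np.ndarray) -> tuple[float, float]:
    """Perimeter and area of an ordered polygon, by explicit summation."""
    verts = np.asarray(verts, dtype=float)
    n = len(verts)
    per = sum(math.dist(verts[i], verts[(i + 1) % n]) for i in range(n))
    area = 0.5 * abs(
        sum(
            verts[i][0] * verts[(i + 1) % n][1]
            - verts[(i + 1) % n][0] * verts[i][1]
            for i in range(n)
        )
    )
    return per, area
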