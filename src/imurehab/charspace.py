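"""Characteristic-space analysis: per-window acceleration summaries and
cluster-region overlap testing.

Each window is summarized as a point (max acceleration, mean acceleration)
on a chosen axis; exercise clusters occupy polygonal regions of that plane.
Two regions overlap when any pair of boundary segments intersects within
both segments, or when one region lies entirely inside the other (the
vertex-containment extension — boundary tests alone would miss full
containment).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.spatial import ConvexHull

from .features import WINDOW_TICKS, MotionWindow

_AXES = {"x": "ax", "y": "ay", "z": "az"}
_EPS = 1e-12

__all__ = [
    "CharPoint",
    "ClusterRegion",
    "char_points",
    "segment_intersection",
    "point_in_polygon",
    "regions_overlap",
]


@dataclass(frozen=True)
class CharPoint:
    """Per-window acceleration summary: (a_max, a_avg) plus its exercise."""

    a_max: float
    a_avg: float
    label: int | None = None

    def __post_init__(self):
        if self.a_max < self.a_avg - 1e-12:
            raise ValueError("max cannot fall below the mean of the same values")


@dataclass(frozen=True)
class ClusterRegion:
    """Polygonal cluster footprint in the (a_max, a_avg) plane."""

    label: int | None
    vertices: np.ndarray  # (k, 2), ordered boundary

    def __post_init__(self):
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] != 2:
            raise ValueError("a region needs at least 3 (x, y) vertices")
        if abs(_polygon_area(v)) < _EPS:
            raise ValueError("degenerate (zero-area) polygon")

    @classmethod
    def from_points(cls, points: Sequence[CharPoint], label: int | None = None) -> "ClusterRegion":
        """Convex hull of labeled characteristic points."""
        xy = np.array([(p.a_max, p.a_avg) for p in points])
        hull = ConvexHull(xy)
        return cls(label=label, vertices=xy[hull.vertices])

    def edges(self):
        v = np.asarray(self.vertices, dtype=float)
        return [(v[i], v[(i + 1) % len(v)]) for i in range(len(v))]


def _polygon_area(v: np.ndarray) -> float:
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))


def char_points(windows: Sequence[MotionWindow], axis: str = "z") -> list[CharPoint]:
    """Max and mean of one acceleration component over each window."""
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}, got {axis!r}")
    if not windows:
        raise ValueError("windows must be nonempty")
    pts = []
    for w in windows:
        block = w.feature(_AXES[axis])
        assert len(block) == WINDOW_TICKS
        pts.append(CharPoint(a_max=float(block.max()), a_avg=float(block.mean()), label=w.label))
    return pts


def segment_intersection(p_i, p_j, p_m, p_n) -> tuple[float, float] | None:
    """Intersection of segments (p_i, p_j) and (p_m, p_n), or None.

    Solves the two supporting lines in general (parametric) form — the
    slope/intercept formulation breaks down for vertical segments — and
    accepts the crossing point only when it falls strictly inside both
    segments' coordinate intervals taken min-to-max, which is the
    containment condition with the intervals normalized so segments stated
    with descending coordinates behave the same.  Parallel (and collinear)
    segments return None.
    """
    p_i, p_j, p_m, p_n = (np.asarray(p, dtype=float) for p in (p_i, p_j, p_m, p_n))
    if np.allclose(p_i, p_j) or np.allclose(p_m, p_n):
        raise ValueError("segments must have distinct endpoints")
    d1 = p_j - p_i
    d2 = p_n - p_m
    denom = d1[0] * d2[1] - d1[1] * d2[0]
    scale = max(np.abs(d1).max(), np.abs(d2).max())
    if abs(denom) < _EPS * scale * scale:
        return None  # parallel slopes
    rhs = p_m - p_i
    s = (rhs[0] * d2[1] - rhs[1] * d2[0]) / denom
    u = (rhs[0] * d1[1] - rhs[1] * d1[0]) / denom
    # strict interiority on both segments == normalized strict interval test
    if not (_EPS < s < 1.0 - _EPS and _EPS < u < 1.0 - _EPS):
        return None
    x0, y0 = p_i + s * d1
    return (float(x0), float(y0))


def point_in_polygon(point, vertices) -> bool:
    """Strict interior test by ray casting (boundary points are outside)."""
    x, y = float(point[0]), float(point[1])
    v = np.asarray(vertices, dtype=float)
    n = len(v)
    inside = False
    for i in range(n):
        x1, y1 = v[i]
        x2, y2 = v[(i + 1) % n]
        # on-edge => not strictly inside
        cross = (x2 - x1) * (y - y1) - (y2 - y1) * (x - x1)
        if (
            abs(cross) < _EPS
            and min(x1, x2) - _EPS <= x <= max(x1, x2) + _EPS
            and min(y1, y2) - _EPS <= y <= max(y1, y2) + _EPS
        ):
            return False
        if (y1 > y) != (y2 > y):
            x_at = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
            if x_at > x:
                inside = not inside
    return inside


def regions_overlap(a: ClusterRegion, b: ClusterRegion) -> bool:
    """True iff boundary segments of the two regions cross, or one region's
    vertex lies strictly inside the other (containment extension)."""
    for e1_start, e1_end in a.edges():
        for e2_start, e2_end in b.edges():
            if segment_intersection(e1_start, e1_end, e2_start, e2_end) is not None:
                return True
    va = np.asarray(a.vertices, dtype=float)
    vb = np.asarray(b.vertices, dtype=float)
    if any(point_in_polygon(p, vb) for p in va):
        return True
    if any(point_in_polygon(p, va) for p in vb):
        return True
    # coincident regions: every vertex sits on the other's boundary, so fall
    # back to the centroids (strictly interior for convex cluster regions)
    if point_in_polygon(va.mean(axis=0), vb) or point_in_polygon(vb.mean(axis=0), va):
        return True
    return False
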