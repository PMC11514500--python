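"""Planar geometry primitives for hotspot selection.

All selector math is done in millimetres in a single coordinate frame:
0-based pixel coordinates with origin at the top-left of the slide, x
rightward and y downward, converted to mm via the scan resolution
(micrometres per pixel).  Containment is *closed* throughout — a point on a
polygon boundary counts as inside — so detections sitting exactly on a hull
through them are always enclosed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import Point as _ShPoint
from shapely.geometry import Polygon as _ShPolygon

#: signed-area tolerance (mm^2) for collinearity and containment decisions
EPS_AREA = 1e-12


@dataclass(frozen=True)
class ResolutionSpec:
    """Scan resolution in micrometres per pixel (0.23 for the study's scanner)."""

    mpp: float = 0.23

    def __post_init__(self) -> None:
        if not np.isfinite(self.mpp) or self.mpp <= 0:
            raise ValueError(f"mpp must be a positive finite number, got {self.mpp}")


def px_to_mm(x_px, y_px, res: ResolutionSpec):
    """Convert pixel coordinates to mm (each coordinate times mpp/1000)."""
    f = res.mpp / 1000.0
    return np.asarray(x_px, dtype=float) * f, np.asarray(y_px, dtype=float) * f


def mm_to_px(x_mm, y_mm, res: ResolutionSpec):
    """Inverse of :func:`px_to_mm`."""
    f = 1000.0 / res.mpp
    return np.asarray(x_mm, dtype=float) * f, np.asarray(y_mm, dtype=float) * f


def _as_points(points) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.size == 0:
        return pts.reshape(0, 2)
    if pts.ndim == 1:
        pts = pts.reshape(1, -1)
    if pts.shape[-1] != 2:
        raise ValueError(f"expected (n, 2) point array, got shape {pts.shape}")
    return pts


def signed_area(vertices) -> float:
    """Shoelace signed area; positive for counterclockwise vertex order."""
    v = _as_points(vertices)
    if len(v) < 3:
        return 0.0
    x, y = v[:, 0], v[:, 1]
    return 0.5 * float(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


def polygon_area(vertices) -> float:
    """Absolute shoelace area in mm²; degenerate polygons (<3 vertices) have area 0."""
    v = _as_points(vertices)
    if len(v) < 1:
        raise ValueError("polygon needs at least one vertex")
    return abs(signed_area(v))


def _cross(o: np.ndarray, a: np.ndarray, b: np.ndarray) -> float:
    """z of (a-o) x (b-o); >0 when o→a→b turns counterclockwise."""
    return float((a[0] - o[0]) * (b[1] - o[1]) - (a[1] - o[1]) * (b[0] - o[0]))


def convex_hull(points, eps: float = EPS_AREA) -> np.ndarray:
    """Gift-wrapped convex hull of a point set.

    Returns hull vertices in counterclockwise order with no three consecutive
    collinear vertices.  Coincident input points are treated as one location;
    1–2 distinct locations give a degenerate (area-0) hull of 1–2 vertices.
    """
    pts = _as_points(points)
    if len(pts) == 0:
        raise ValueError("convex hull of an empty point set is undefined")
    uniq = np.unique(pts, axis=0)  # lexicographic (x, then y) sort
    m = len(uniq)
    if m == 1:
        return uniq.copy()
    if m == 2:
        return uniq.copy()
    # all-collinear degenerate case: endpoints of the lexicographic sort
    first, last = uniq[0], uniq[-1]
    if all(abs(_cross(first, last, p)) <= eps for p in uniq):
        return np.vstack([first, last])

    start = 0  # lexicographic minimum is always a hull vertex
    hull_idx = [start]
    cur = start
    while True:
        cand = (cur + 1) % m
        for i in range(m):
            if i == cur:
                continue
            c = _cross(uniq[cur], uniq[cand], uniq[i])
            if c < -eps:
                cand = i  # i lies right of cur→cand, so cand is not a hull edge
            elif abs(c) <= eps:
                # collinear: keep the farthest so interior collinear points drop out
                if np.sum((uniq[i] - uniq[cur]) ** 2) > np.sum(
                    (uniq[cand] - uniq[cur]) ** 2
                ):
                    cand = i
        if cand == start:
            break
        hull_idx.append(cand)
        cur = cand
        if len(hull_idx) > m:  # numerical safety; cannot happen for clean input
            raise RuntimeError("gift wrapping failed to close the hull")
    verts = uniq[hull_idx]
    if signed_area(verts) < 0:
        verts = verts[::-1]
    return verts


def points_in_convex_polygon(hull, points, eps: float = EPS_AREA) -> np.ndarray:
    """Closed containment of many points in a convex polygon (CCW vertices).

    Degenerate hulls are supported: a single vertex matches coincident points,
    a two-vertex hull matches points on the closed segment.
    """
    h = _as_points(hull)
    pts = _as_points(points)
    if len(pts) == 0:
        return np.zeros(0, dtype=bool)
    if len(h) == 1:
        return np.all(np.abs(pts - h[0]) <= 1e-9, axis=1)
    if len(h) == 2:
        a, b = h
        d = b - a
        r = pts - a
        cross = d[0] * r[:, 1] - d[1] * r[:, 0]
        dot = r @ d
        return (np.abs(cross) <= eps) & (dot >= -eps) & (dot <= d @ d + eps)
    inside = np.ones(len(pts), dtype=bool)
    for i in range(len(h)):
        a, b = h[i], h[(i + 1) % len(h)]
        d = b - a
        r = pts - a
        inside &= d[0] * r[:, 1] - d[1] * r[:, 0] >= -eps
    return inside


@dataclass(frozen=True)
class PolygonMM:
    """A polygon with vertices in mm (implicitly closed).

    Tumor annotations may be arbitrary simple polygons; hulls produced by this
    package are counterclockwise and strictly convex.  Degenerate polygons of
    1–2 vertices are permitted and have area 0.
    """

    vertices: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        v = _as_points(self.vertices)
        if len(v) < 1:
            raise ValueError("polygon needs at least one vertex")
        if not np.all(np.isfinite(v)):
            raise ValueError("polygon vertices must be finite")
        object.__setattr__(self, "vertices", v)

    @property
    def area(self) -> float:
        return polygon_area(self.vertices)

    def to_shapely(self) -> _ShPolygon:
        if len(self.vertices) < 3:
            raise ValueError("degenerate polygon has no shapely representation")
        return _ShPolygon(self.vertices)

    def contains(self, x: float, y: float, eps: float = EPS_AREA) -> bool:
        """Closed point-in-polygon test (boundary counts as inside)."""
        v = self.vertices
        if len(v) < 3:
            return bool(points_in_convex_polygon(v, [[x, y]], eps)[0])
        return bool(self.to_shapely().covers(_ShPoint(x, y)))

    def contains_points(self, points, eps: float = EPS_AREA) -> np.ndarray:
        pts = _as_points(points)
        v = self.vertices
        if len(v) < 3:
            return points_in_convex_polygon(v, pts, eps)
        import shapely

        sh = self.to_shapely()
        return np.asarray(shapely.covers(sh, shapely.points(pts)), dtype=bool)
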