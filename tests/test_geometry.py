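"""Geometric primitives: unit conversion, shoelace area, gift-wrapped hull,
closed containment."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mitohotspot import PolygonMM, ResolutionSpec, convex_hull, mm_to_px, polygon_area, px_to_mm
from mitohotspot.geometry import points_in_convex_polygon, signed_area


@pytest.mark.parametrize(
    "x_px, y_px, mpp, expected",
    [
        (0, 0, 0.23, (0.0, 0.0)),
        (1000, 0, 1.0, (1.0, 0.0)),
        (1000 / 0.23, 1000 / 0.23, 0.23, (1.0, 1.0)),
    ],
)
def test_px_to_mm(x_px, y_px, mpp, expected):
    x, y = px_to_mm(x_px, y_px, ResolutionSpec(mpp))
    assert np.allclose([x, y], expected)


def test_px_mm_roundtrip():
    res = ResolutionSpec(0.23)
    rng = np.random.default_rng(11)
    pts = rng.uniform(0, 2e5, size=(500, 2))
    xm, ym = px_to_mm(pts[:, 0], pts[:, 1], res)
    xb, yb = mm_to_px(xm, ym, res)
    assert np.allclose(np.column_stack([xb, yb]), pts, rtol=1e-9)


def test_non_positive_mpp_rejected():
    with pytest.raises(ValueError):
        ResolutionSpec(0.0)


@pytest.mark.parametrize(
    "vertices, expected",
    [
        ([[0, 0], [1, 0], [1, 1], [0, 1]], 1.0),
        ([[0, 0], [1, 1]], 0.0),
        ([[0, 0], [1, 0], [5, 5], [0, 1]], 5.0),  # hand shoelace: |0+5+5+0|/2
    ],
)
def test_polygon_area(vertices, expected):
    assert polygon_area(vertices) == pytest.approx(expected)


def test_hull_excludes_interior_point(unit_square):
    hull = convex_hull(np.vstack([unit_square.vertices, [[0.5, 0.5]]]))
    assert len(hull) == 4
    assert signed_area(hull) > 0  # counterclockwise
    assert {tuple(v) for v in hull} == {(0, 0), (1, 0), (1, 1), (0, 1)}


def test_hull_of_collinear_points_is_segment():
    hull = convex_hull([[0, 0], [1, 1], [2, 2]])
    assert len(hull) == 2
    assert {tuple(v) for v in hull} == {(0, 0), (2, 2)}


def test_hull_of_empty_set_rejected():
    with pytest.raises(ValueError):
        convex_hull(np.zeros((0, 2)))


def _triangle_contains(a, b, c, p, eps=1e-12):
    d1 = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
    d2 = (c[0] - b[0]) * (p[1] - b[1]) - (c[1] - b[1]) * (p[0] - b[0])
    d3 = (a[0] - c[0]) * (p[1] - c[1]) - (a[1] - c[1]) * (p[0] - c[0])
    neg = (d1 < -eps) or (d2 < -eps) or (d3 < -eps)
    pos = (d1 > eps) or (d2 > eps) or (d3 > eps)
    return not (neg and pos)


def _on_segment(a, b, p, eps=1e-12):
    cross = (b[0] - a[0]) * (p[1] - a[1]) - (b[1] - a[1]) * (p[0] - a[0])
    if abs(cross) > eps:
        return False
    dot = (p[0] - a[0]) * (b[0] - a[0]) + (p[1] - a[1]) * (b[1] - a[1])
    return -eps <= dot <= (b[0] - a[0]) ** 2 + (b[1] - a[1]) ** 2 + eps


def brute_force_hull_vertices(points) -> set:
    """O(n³)+ reference: p is a hull vertex iff it is not inside the hull of
    the others, i.e. (Carathéodory in the plane) not in any triangle or on any
    segment spanned by the other points."""
    pts = [tuple(p) for p in np.unique(np.asarray(points, float), axis=0)]
    verts = set()
    for p in pts:
        others = [q for q in pts if q != p]
        covered = any(
            _triangle_contains(a, b, c, p)
            for a, b, c in itertools.combinations(others, 3)
        ) or any(_on_segment(a, b, p) for a, b in itertools.combinations(others, 2))
        if not covered:
            verts.add(p)
    return verts


def test_hull_matches_brute_force_reference():
    rng = np.random.default_rng(42)
    for _ in range(200):
        n = int(rng.integers(3, 16))
        pts = rng.uniform(0, 10, size=(n, 2))
        hull = convex_hull(pts)
        assert {tuple(v) for v in hull} == brute_force_hull_vertices(pts)


def test_hull_contains_all_points_and_subset_area_monotone():
    rng = np.random.default_rng(3)
    for _ in range(50):
        pts = rng.uniform(0, 5, size=(int(rng.integers(3, 20)), 2))
        hull = convex_hull(pts)
        assert points_in_convex_polygon(hull, pts).all()
        sub = pts[rng.random(len(pts)) < 0.6]
        if len(sub) >= 1:
            assert polygon_area(convex_hull(sub)) <= polygon_area(hull) + 1e-12


@pytest.mark.parametrize(
    "point, expected",
    [((0.5, 0.5), True), ((1.0, 0.5), True), ((1.0001, 0.5), False)],
)
def test_closed_containment(unit_square, point, expected):
    assert unit_square.contains(*point) is expected


# slide coordinates are pixel-quantized (>= 0.1 µm granularity), so sample a
# coarse lattice (many exact duplicates and collinear triples) and a fine
# 0.1 µm lattice (general position) instead of adversarial raw floats
coord = st.one_of(
    st.integers(0, 40).map(lambda i: i * 0.5),
    st.integers(0, 200_000).map(lambda i: i * 1e-4),
)


@settings(max_examples=150, derandomize=True, deadline=None)
@given(st.lists(st.tuples(coord, coord), min_size=1, max_size=25))
def test_hull_invariants_hold_for_arbitrary_point_sets(points):
    pts = np.array(points)
    hull = convex_hull(pts)
    # every input point is enclosed (closed containment)
    assert points_in_convex_polygon(hull, pts).all()
    # hull orientation and non-degeneracy of the vertex list
    if len(hull) >= 3:
        assert signed_area(hull) > 0
    # the hull of the hull is the hull (idempotence)
    again = convex_hull(hull)
    assert {tuple(v) for v in again} == {tuple(v) for v in hull}
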