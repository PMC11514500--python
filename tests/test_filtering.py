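"""Probability thresholding and tumor-area containment filters."""

import numpy as np
import pytest

from mitohotspot import (
    PolygonMM,
    ResolutionSpec,
    TumorAnnotation,
    ValidationError,
    threshold_filter,
    tumor_filter,
)
from mitohotspot.io import DetectionCandidate

RES = ResolutionSpec(1000.0)  # 1 px = 1 mm: px and mm coordinates coincide


def _cand(i, x, y, prob, slide="S1"):
    return DetectionCandidate(f"c{i}", slide, float(x), float(y), float(prob))


def _annot(vertices, slide="S1"):
    return TumorAnnotation(slide_id=slide, polygons=(PolygonMM(np.asarray(vertices, float)),))


SQUARE = [[0, 0], [10, 0], [10, 10], [0, 10]]


def test_threshold_is_closed_at_the_operating_point():
    cands = [_cand(i, i, 0, p) for i, p in enumerate([0.63, 0.64, 0.90])]
    kept = threshold_filter(cands, 0.64)
    assert [c.probability for c in kept] == [0.64, 0.90]


def test_threshold_extremes():
    cands = [_cand(i, 0, 0, p) for i, p in enumerate([0.0, 0.5, 1.0])]
    assert threshold_filter(cands, 0.0) == cands
    assert [c.probability for c in threshold_filter(cands, 1.0)] == [1.0]


def test_threshold_monotone_and_idempotent():
    rng = np.random.default_rng(5)
    cands = [_cand(i, 0, 0, p) for i, p in enumerate(rng.uniform(size=50))]
    for t1, t2 in [(0.2, 0.7), (0.0, 0.64), (0.64, 0.65)]:
        keep1, keep2 = threshold_filter(cands, t1), threshold_filter(cands, t2)
        assert set(c.candidate_id for c in keep2) <= set(c.candidate_id for c in keep1)
        assert threshold_filter(keep1, t1) == keep1


def test_tumor_filter_counts_and_containment():
    inside = [_cand(i, 1 + i, 5, 0.9) for i in range(5)]
    outside = [_cand(10 + i, 20 + i, 5, 0.9) for i in range(3)]
    fd = tumor_filter(inside + outside, _annot(SQUARE), RES)
    assert (fd.n_raw, fd.n_after_threshold, fd.n_after_tumor) == (8, 8, 5)
    assert len(fd.points) == 5


def test_candidate_on_edge_is_kept():
    fd = tumor_filter([_cand(0, 10.0, 5.0, 0.9)], _annot(SQUARE), RES)
    assert fd.n_after_tumor == 1


def test_tumor_filter_validation():
    with pytest.raises(ValidationError):
        tumor_filter([_cand(0, 0, 0, 0.9)], TumorAnnotation("S1", polygons=()), RES)
    with pytest.raises(ValidationError):
        tumor_filter([_cand(0, 0, 0, 0.9, slide="S2")], _annot(SQUARE), RES)


def test_filter_order_commutes_as_sets():
    rng = np.random.default_rng(8)
    cands = [
        _cand(i, rng.uniform(0, 15), rng.uniform(0, 15), rng.uniform())
        for i in range(200)
    ]
    annot = _annot(SQUARE)
    t = 0.64
    thresh_then_tumor = tumor_filter(threshold_filter(cands, t), annot, RES).points
    # reverse order: spatial filter on everything, then thresholding by hand
    poly = annot.polygons[0]
    in_tumor = [c for c in cands if poly.contains(c.x_px / 1000 * RES.mpp, c.y_px / 1000 * RES.mpp)]
    tumor_then_thresh = np.array(
        [[c.x_px / 1000 * RES.mpp, c.y_px / 1000 * RES.mpp] for c in threshold_filter(in_tumor, t)]
    ).reshape(-1, 2)
    assert {tuple(p) for p in thresh_then_tumor} == {tuple(p) for p in tumor_then_thresh}


def test_tumor_filter_idempotent_on_points():
    rng = np.random.default_rng(9)
    cands = [_cand(i, rng.uniform(0, 10), rng.uniform(0, 10), 0.9) for i in range(50)]
    once = tumor_filter(cands, _annot(SQUARE), RES)
    again_cands = [
        _cand(i, p[0], p[1], 0.9) for i, p in enumerate(once.points)
    ]
    twice = tumor_filter(again_cands, _annot(SQUARE), RES)
    assert np.allclose(np.sort(once.points, axis=0), np.sort(twice.points, axis=0))
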