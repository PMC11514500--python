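"""Candidate filtering: probability threshold, then tumor-area containment.

Both comparisons are closed: a candidate at exactly the operating point is
accepted, and a candidate exactly on the tumor outline is inside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import ResolutionSpec, px_to_mm
from .io import DetectionCandidate, TumorAnnotation, ValidationError


@dataclass(frozen=True)
class FilteredDetections:
    """Accepted mitotic figures of one slide, with the filter audit trail."""

    slide_id: str
    points: np.ndarray  # (n, 2) mm coordinates of accepted candidates
    n_raw: int
    n_after_threshold: int
    n_after_tumor: int

    def __post_init__(self) -> None:
        if not self.n_raw >= self.n_after_threshold >= self.n_after_tumor:
            raise ValidationError("filter counts must be non-increasing")
        if self.n_after_tumor != len(self.points):
            raise ValidationError("n_after_tumor must equal the number of points")


def threshold_filter(
    cands: list[DetectionCandidate], t: float
) -> list[DetectionCandidate]:
    """Keep candidates with probability >= t (order preserved)."""
    if not 0.0 <= t <= 1.0:
        raise ValueError(f"threshold must be in [0, 1], got {t}")
    return [c for c in cands if c.probability >= t]


def tumor_filter(
    cands: list[DetectionCandidate],
    annot: TumorAnnotation,
    res: ResolutionSpec,
    *,
    n_raw: int | None = None,
) -> FilteredDetections:
    """Keep candidates inside any tumor polygon (closed containment).

    ``n_raw`` lets the caller record the pre-threshold count in the audit
    trail; it defaults to the number of candidates passed in.
    """
    if not annot.polygons:
        raise ValidationError(f"slide {annot.slide_id}: annotation has no polygons")
    for c in cands:
        if c.slide_id != annot.slide_id:
            raise ValidationError(
                f"candidate {c.candidate_id} is from slide {c.slide_id!r}, "
                f"annotation is for {annot.slide_id!r}"
            )
    n_in = len(cands)
    if n_raw is None:
        n_raw = n_in
    if cands:
        x, y = px_to_mm(
            [c.x_px for c in cands], [c.y_px for c in cands], res
        )
        pts = np.column_stack([x, y])
        keep = np.zeros(n_in, dtype=bool)
        for poly in annot.polygons:
            keep |= poly.contains_points(pts)
        points = pts[keep]
    else:
        points = np.zeros((0, 2))
    return FilteredDetections(
        slide_id=annot.slide_id,
        points=points,
        n_raw=n_raw,
        n_after_threshold=n_in,
        n_after_tumor=len(points),
    )
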