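"""Case-level aggregation and Bloom–Richardson mitotic scoring.

When a case has several slides (or several tumors on one slide), the slide
and tumor with the highest mitotic count win, mirroring the diagnostic
workflow of grading the most proliferative tumor area.  The count is then
mapped to the mitotic component of the Bloom–Richardson grade using the
College of American Pathologists cut-offs for a 2 mm² area: MC ≤ 7 scores 1,
8–14 scores 2, ≥ 15 scores 3.  Counts are reported per selected region (area
≤ 2 mm²) with no area normalization.
"""

from __future__ import annotations

from dataclasses import dataclass


@dataclass(frozen=True)
class SlideResult:
    """Mitotic count of one slide (or one tumor on a slide) by one method."""

    case_id: str
    slide_id: str
    mc: int
    method: str
    tumor_id: str | None = None

    def __post_init__(self) -> None:
        if self.mc < 0:
            raise ValueError("mitotic count must be non-negative")


@dataclass(frozen=True)
class CaseScore:
    """Per-case mitotic count and BR mitotic score with provenance."""

    case_id: str
    mc: int
    br_score: int
    winning_slide_id: str
    winning_tumor_id: str | None = None
    method: str = ""


def br_mitotic_score(mc: int) -> int:
    """BR mitotic score: 1 for MC ≤ 7, 2 for 8–14, 3 for MC ≥ 15."""
    if mc < 0:
        raise ValueError(f"mitotic count must be non-negative, got {mc}")
    if mc <= 7:
        return 1
    if mc <= 14:
        return 2
    return 3


def aggregate_case(slides: list[SlideResult]) -> tuple[int, str, str | None]:
    """Maximum MC over a case's slides and tumors, with the winner's ids.

    Ties break lexicographically on slide_id, then tumor_id, so repeated runs
    pick the same winner.
    """
    if not slides:
        raise ValueError("aggregate_case needs at least one slide result")
    case_ids = {s.case_id for s in slides}
    if len(case_ids) != 1:
        raise ValueError(f"mixed case_ids in aggregation: {sorted(case_ids)}")
    winner = min(slides, key=lambda s: (-s.mc, s.slide_id, s.tumor_id or ""))
    return winner.mc, winner.slide_id, winner.tumor_id


def score_case(slides: list[SlideResult]) -> CaseScore:
    """Aggregate one case's slide results into a CaseScore."""
    mc, slide_id, tumor_id = aggregate_case(slides)
    methods = {s.method for s in slides}
    return CaseScore(
        case_id=slides[0].case_id,
        mc=mc,
        br_score=br_mitotic_score(mc),
        winning_slide_id=slide_id,
        winning_tumor_id=tumor_id,
        method=methods.pop() if len(methods) == 1 else "mixed",
    )
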