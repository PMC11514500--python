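"""End-to-end orchestration: detections + annotations → hotspot MCs → scores.

The flow mirrors the clinical pipeline: threshold the detector output at the
operating point, discard candidates outside the tumor outline, run the
requested area selector(s) on what remains, and aggregate slide/tumor counts
to a per-case mitotic count and BR mitotic score.  Slides lacking an
annotation are reported as skipped; a failure on one slide does not abort the
others.
"""

from __future__ import annotations

import logging
import time
from collections import defaultdict
from dataclasses import dataclass, field
from datetime import datetime, timezone

from .bame_selector import bame_select
from .config import RunConfig
from .filtering import FilteredDetections, threshold_filter, tumor_filter
from .io import (
    DetectionCandidate,
    TumorAnnotation,
    read_annotations,
    read_detections,
    write_report,
)
from .scoring import CaseScore, SlideResult, score_case
from .window_selector import HotspotResult, default_window, window_search

logger = logging.getLogger("mitohotspot")

METHODS = ("window", "bame")


class PipelineError(RuntimeError):
    """The run as a whole could not proceed (e.g. no joinable slides)."""


@dataclass
class RunManifest:
    """Everything one pipeline run produced, for the JSON report."""

    config: RunConfig
    input_files: list[str]
    slide_summaries: list[dict] = field(default_factory=list)
    hotspot_results: list[HotspotResult] = field(default_factory=list)
    case_scores: list[CaseScore] = field(default_factory=list)
    skipped_slides: list[str] = field(default_factory=list)
    failed_slides: list[str] = field(default_factory=list)
    started_at: str = ""
    finished_at: str = ""


def _process_slide(
    cands: list[DetectionCandidate],
    annot: TumorAnnotation,
    cfg: RunConfig,
    methods: tuple[str, ...],
) -> tuple[FilteredDetections, list[HotspotResult]]:
    res = cfg.resolution
    kept = threshold_filter(cands, cfg.prob_threshold)
    audit = tumor_filter(kept, annot, res, n_raw=len(cands))
    logger.info(
        "slide %s: %d raw -> %d above threshold -> %d in tumor",
        annot.slide_id,
        audit.n_raw,
        audit.n_after_threshold,
        audit.n_after_tumor,
    )
    # multi-tumor slides are selected per tumor so the scoring stage can pick
    # the most proliferative tumor
    groups: dict[str | None, list[int]] = defaultdict(list)
    for i, tid in enumerate(annot.tumor_ids):
        groups[tid].append(i)
    results = []
    for tumor_id, poly_idx in sorted(groups.items(), key=lambda kv: (kv[0] is not None, kv[0])):
        sub_annot = TumorAnnotation(
            slide_id=annot.slide_id,
            polygons=tuple(annot.polygons[i] for i in poly_idx),
            tumor_ids=tuple(annot.tumor_ids[i] for i in poly_idx),
        )
        pts = tumor_filter(kept, sub_annot, res).points
        for method in methods:
            t0 = time.perf_counter()
            if method == "window":
                hr = window_search(
                    pts, default_window(cfg), slide_id=annot.slide_id, tumor_id=tumor_id
                )
            elif method == "bame":
                hr = bame_select(pts, cfg, slide_id=annot.slide_id, tumor_id=tumor_id)
            else:
                raise ValueError(f"unknown method {method!r}")
            logger.info(
                "slide %s tumor %s: %s mc=%d (%.3f s)",
                annot.slide_id,
                tumor_id,
                method,
                hr.mc,
                time.perf_counter() - t0,
            )
            results.append(hr)
    return audit, results


def run_pipeline(
    detections_path,
    annotations_path,
    cfg: RunConfig | None = None,
    methods: tuple[str, ...] = METHODS,
    out_dir=None,
) -> RunManifest:
    """Run the full pipeline from files; optionally write the report bundle."""
    cfg = cfg or RunConfig()
    for m in methods:
        if m not in METHODS:
            raise ValueError(f"unknown method {m!r}; choose from {METHODS}")
    manifest = RunManifest(
        config=cfg,
        input_files=[str(detections_path), str(annotations_path)],
        started_at=datetime.now(timezone.utc).isoformat(),
    )
    logger.info("config: %s", cfg.to_dict())

    candidates = read_detections(detections_path)
    annots = read_annotations(annotations_path, cfg.resolution)
    by_slide: dict[str, list[DetectionCandidate]] = defaultdict(list)
    for c in candidates:
        by_slide[c.slide_id].append(c)

    joinable = sorted(set(by_slide) & set(annots))
    manifest.skipped_slides = sorted(set(by_slide) - set(annots))
    if not joinable:
        raise PipelineError(
            "no slide_id is shared between the detections and the annotations"
        )
    for sid in manifest.skipped_slides:
        logger.warning("slide %s has no annotation; skipped", sid)

    slide_case: dict[str, str] = {}
    slide_results: list[SlideResult] = []
    for sid in joinable:
        cands = by_slide[sid]
        case_id = next((c.case_id for c in cands if c.case_id), sid)
        slide_case[sid] = case_id
        try:
            audit, results = _process_slide(cands, annots[sid], cfg, methods)
        except Exception:
            logger.exception("slide %s failed; continuing with the others", sid)
            manifest.failed_slides.append(sid)
            continue
        manifest.slide_summaries.append(
            {
                "slide_id": sid,
                "case_id": case_id,
                "n_raw": audit.n_raw,
                "n_after_threshold": audit.n_after_threshold,
                "n_after_tumor": audit.n_after_tumor,
            }
        )
        manifest.hotspot_results.extend(results)
        slide_results.extend(
            SlideResult(
                case_id=case_id,
                slide_id=sid,
                mc=hr.mc,
                method=hr.method,
                tumor_id=hr.tumor_id,
            )
            for hr in results
        )

    by_case_method: dict[tuple[str, str], list[SlideResult]] = defaultdict(list)
    for sr in slide_results:
        by_case_method[(sr.case_id, sr.method)].append(sr)
    manifest.case_scores = [
        score_case(group) for _, group in sorted(by_case_method.items())
    ]
    manifest.finished_at = datetime.now(timezone.utc).isoformat()

    if out_dir is not None:
        write_report(
            out_dir,
            config=cfg,
            slide_summaries=manifest.slide_summaries,
            hotspot_results=manifest.hotspot_results,
            case_scores=manifest.case_scores,
            skipped_slides=manifest.skipped_slides,
        )
    return manifest
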