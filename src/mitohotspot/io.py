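"""File formats: detection CSV, tumor-outline GeoJSON, JSON/GeoJSON reports.

Detections are exchanged as a detector-agnostic CSV (columns ``candidate_id,
slide_id, x_px, y_px, probability``, plus an optional ``case_id``).  Tumor
outlines are GeoJSON FeatureCollections of (Multi)Polygons in pixel
coordinates, the de facto export of slide-annotation tools.  Reports are JSON
plus a GeoJSON of the selected hotspot regions in pixel coordinates.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .geometry import PolygonMM, ResolutionSpec, mm_to_px, px_to_mm

DETECTION_COLUMNS = ("candidate_id", "slide_id", "x_px", "y_px", "probability")


class FormatError(ValueError):
    """Input file does not match the expected schema."""


class ValidationError(ValueError):
    """Input parses but violates a field invariant."""


@dataclass(frozen=True)
class DetectionCandidate:
    """One detector output: a location in pixels plus a probability score."""

    candidate_id: str
    slide_id: str
    x_px: float
    y_px: float
    probability: float
    case_id: str | None = None

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x_px) and np.isfinite(self.y_px)):
            raise ValidationError(f"candidate {self.candidate_id}: non-finite coordinates")
        if self.x_px < 0 or self.y_px < 0:
            raise ValidationError(f"candidate {self.candidate_id}: negative coordinates")
        if not 0.0 <= self.probability <= 1.0:
            raise ValidationError(
                f"candidate {self.candidate_id}: probability {self.probability} outside [0, 1]"
            )


@dataclass(frozen=True)
class TumorAnnotation:
    """Polygon(s) delimiting the tumor area of one slide, in mm."""

    slide_id: str
    polygons: tuple[PolygonMM, ...]
    tumor_ids: tuple[str | None, ...] = field(default=())

    def __post_init__(self) -> None:
        if not self.tumor_ids:
            object.__setattr__(self, "tumor_ids", (None,) * len(self.polygons))
        if len(self.tumor_ids) != len(self.polygons):
            raise ValidationError("tumor_ids must parallel polygons")
        for poly in self.polygons:
            if len(poly.vertices) < 3:
                raise ValidationError("tumor polygons need at least 3 vertices")


def read_detections(path) -> list[DetectionCandidate]:
    """Read a detection-candidate CSV; row order is preserved."""
    df = pd.read_csv(path, dtype={"candidate_id": str, "slide_id": str, "case_id": str})
    missing = [c for c in DETECTION_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s) {', '.join(missing)}")
    has_case = "case_id" in df.columns
    out = []
    for i, row in enumerate(df.itertuples(index=False)):
        prob = float(row.probability)
        if not 0.0 <= prob <= 1.0:
            raise ValidationError(
                f"{path} row {i + 2}: probability {prob} outside [0, 1]"
            )
        out.append(
            DetectionCandidate(
                candidate_id=str(row.candidate_id),
                slide_id=str(row.slide_id),
                x_px=float(row.x_px),
                y_px=float(row.y_px),
                probability=prob,
                case_id=str(row.case_id) if has_case and pd.notna(row.case_id) else None,
            )
        )
    return out


def write_detections(candidates: list[DetectionCandidate], path) -> None:
    rows = []
    for c in candidates:
        row = {k: getattr(c, k) for k in DETECTION_COLUMNS}
        if c.case_id is not None:
            row["case_id"] = c.case_id
        rows.append(row)
    cols = list(DETECTION_COLUMNS) + (
        ["case_id"] if any("case_id" in r for r in rows) else []
    )
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def _ring_to_polygon(ring, res: ResolutionSpec) -> PolygonMM:
    ring = np.asarray(ring, dtype=float)
    if ring.ndim != 2 or ring.shape[1] != 2:
        raise FormatError("polygon ring must be a list of [x, y] pairs")
    if len(ring) > 1 and np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]  # GeoJSON rings repeat the first vertex
    if len(ring) < 3:
        raise ValidationError("polygon ring has fewer than 3 distinct vertices")
    x_mm, y_mm = px_to_mm(ring[:, 0], ring[:, 1], res)
    return PolygonMM(np.column_stack([x_mm, y_mm]))


def read_annotations(path, res: ResolutionSpec) -> dict[str, TumorAnnotation]:
    """Read a GeoJSON of tumor outlines (pixel coordinates), grouped by slide.

    ``slide_id`` is taken from each feature's properties, falling back to the
    file's stem; ``tumor_id`` is preserved when present.  Only exterior rings
    are used.
    """
    path = Path(path)
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") != "FeatureCollection":
        raise FormatError(f"{path}: expected a GeoJSON FeatureCollection")
    by_slide: dict[str, list[tuple[PolygonMM, str | None]]] = {}
    for feat in gj.get("features", []):
        geom = feat.get("geometry") or {}
        props = feat.get("properties") or {}
        gtype = geom.get("type")
        slide_id = str(props.get("slide_id", path.stem))
        tumor_id = props.get("tumor_id")
        tumor_id = None if tumor_id is None else str(tumor_id)
        if gtype == "Polygon":
            rings = [geom["coordinates"][0]]
        elif gtype == "MultiPolygon":
            rings = [poly[0] for poly in geom["coordinates"]]
        else:
            raise FormatError(f"{path}: unsupported geometry type {gtype!r}")
        for ring in rings:
            by_slide.setdefault(slide_id, []).append((_ring_to_polygon(ring, res), tumor_id))
    return {
        sid: TumorAnnotation(
            slide_id=sid,
            polygons=tuple(p for p, _ in items),
            tumor_ids=tuple(t for _, t in items),
        )
        for sid, items in by_slide.items()
    }


def read_annotation(path, res: ResolutionSpec) -> TumorAnnotation:
    """Read a single-slide annotation file (error if it spans several slides)."""
    annots = read_annotations(path, res)
    if len(annots) != 1:
        raise ValidationError(
            f"{path}: expected one slide, found {sorted(annots)}"
        )
    return next(iter(annots.values()))


def write_annotations(
    annots: dict[str, TumorAnnotation] | TumorAnnotation, path, res: ResolutionSpec
) -> None:
    """Write tumor annotations as a pixel-coordinate GeoJSON FeatureCollection."""
    if isinstance(annots, TumorAnnotation):
        annots = {annots.slide_id: annots}
    features = []
    for annot in annots.values():
        for poly, tumor_id in zip(annot.polygons, annot.tumor_ids):
            v = poly.vertices
            x, y = mm_to_px(v[:, 0], v[:, 1], res)
            ring = np.column_stack([x, y]).tolist()
            ring.append(ring[0])
            props = {"slide_id": annot.slide_id}
            if tumor_id is not None:
                props["tumor_id"] = tumor_id
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": props,
                }
            )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=2)


def _region_px(vertices_mm: np.ndarray, res: ResolutionSpec) -> list[list[float]]:
    x, y = mm_to_px(vertices_mm[:, 0], vertices_mm[:, 1], res)
    return np.column_stack([x, y]).tolist()


def write_report(
    out_dir,
    *,
    config,
    slide_summaries: list[dict],
    hotspot_results: list,
    case_scores: list,
    skipped_slides: list[str] = (),
) -> dict[str, Path]:
    """Write report.json, regions.geojson and case_scores.csv under ``out_dir``.

    Selected regions are emitted both in mm (report JSON) and as GeoJSON in
    pixel coordinates, so they can be loaded back into the annotation viewer
    the tumor outlines came from.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    res = ResolutionSpec(config.mpp)

    results_json = []
    features = []
    for hr in hotspot_results:
        verts = hr.region.vertices
        px = _region_px(verts, res)
        entry = {
            "slide_id": hr.slide_id,
            "tumor_id": hr.tumor_id,
            "method": hr.method,
            "mc": int(hr.mc),
            "region_area_mm2": float(hr.region_area_mm2),
            "solver": hr.solver,
            "region_mm": verts.tolist(),
            "region_px": px,
        }
        results_json.append(entry)
        if len(px) >= 3:
            features.append(
                {
                    "type": "Feature",
                    "geometry": {"type": "Polygon", "coordinates": [px + px[:1]]},
                    "properties": {
                        "slide_id": hr.slide_id,
                        "tumor_id": hr.tumor_id,
                        "method": hr.method,
                        "mc": int(hr.mc),
                    },
                }
            )

    report = {
        "config": config.to_dict(),
        "slides": slide_summaries,
        "hotspots": results_json,
        "cases": [
            {
                "case_id": cs.case_id,
                "method": cs.method,
                "mc": int(cs.mc),
                "br_score": int(cs.br_score),
                "winning_slide_id": cs.winning_slide_id,
                "winning_tumor_id": cs.winning_tumor_id,
            }
            for cs in case_scores
        ],
        "skipped_slides": list(skipped_slides),
    }

    paths = {
        "report": out_dir / "report.json",
        "regions": out_dir / "regions.geojson",
        "cases": out_dir / "case_scores.csv",
    }
    with open(paths["report"], "w") as fh:
        json.dump(report, fh, indent=2)
    with open(paths["regions"], "w") as fh:
        json.dump({"type": "FeatureCollection", "features": features}, fh, indent=2)
    pd.DataFrame(
        [
            {
                "case_id": cs.case_id,
                "method": cs.method,
                "mc": int(cs.mc),
                "br_score": int(cs.br_score),
                "winning_slide_id": cs.winning_slide_id,
            }
            for cs in case_scores
        ],
        columns=["case_id", "method", "mc", "br_score", "winning_slide_id"],
    ).to_csv(paths["cases"], index=False)
    return paths


def read_paired_counts(path) -> pd.DataFrame:
    """Read a paired mitotic-count table with columns case_id, mc_a, mc_b."""
    df = pd.read_csv(path, dtype={"case_id": str})
    for col in ("case_id", "mc_a", "mc_b"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col}")
    if (df[["mc_a", "mc_b"]] < 0).any().any():
        raise ValidationError(f"{path}: mitotic counts must be non-negative")
    return df
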