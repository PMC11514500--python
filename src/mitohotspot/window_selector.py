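"""Overlapping fixed-area rectangle search for the mitotic hotspot.

The window is an axis-aligned rectangle of fixed area (2 mm² by default) with
a 4:3 width-over-height ratio.  The grid of candidate positions advances a
quarter of the window dimension per step, covering the bounding box of the
detections expanded by one window dimension on each side; the rectangle
containing the most mitotic figures wins.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .geometry import PolygonMM, polygon_area

_TOL = 1e-9


@dataclass(frozen=True)
class WindowSpec:
    width: float  # mm
    height: float  # mm
    stride_x: float  # mm
    stride_y: float  # mm

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("window dimensions must be positive")
        if not 0 < self.stride_x <= self.width + _TOL:
            raise ValueError("stride_x must be in (0, width]")
        if not 0 < self.stride_y <= self.height + _TOL:
            raise ValueError("stride_y must be in (0, height]")

    @property
    def area(self) -> float:
        return self.width * self.height


@dataclass(frozen=True)
class HotspotResult:
    """A selected hotspot region and the mitotic count inside it."""

    slide_id: str
    method: str  # "window" or "bame"
    region: PolygonMM
    mc: int
    region_area_mm2: float
    solver: str | None = None
    tumor_id: str | None = None


def default_window(cfg: RunConfig) -> WindowSpec:
    """Window forced by the configured area and aspect ratio.

    width = sqrt(area * ratio), height = sqrt(area / ratio); the grid stride is
    ``window_overlap_fraction`` of each dimension (or its complement when the
    overlap is read literally).
    """
    area = cfg.hotspot_area_mm2
    ratio = cfg.window_aspect_w_over_h
    width = math.sqrt(area * ratio)
    height = math.sqrt(area / ratio)
    f = cfg.window_overlap_fraction
    step = (1.0 - f) if cfg.window_literal_overlap else f
    return WindowSpec(width, height, stride_x=step * width, stride_y=step * height)


def _rect(x0: float, y0: float, w: float, h: float) -> PolygonMM:
    return PolygonMM(
        np.array([[x0, y0], [x0 + w, y0], [x0 + w, y0 + h], [x0, y0 + h]])
    )


def window_search(
    points, spec: WindowSpec, *, slide_id: str = "", tumor_id: str | None = None
) -> HotspotResult:
    """Max-count window over the stride grid; ties go to the first grid cell.

    Grid cells are ordered row-major (y outer, x inner) from the expanded
    bounding-box minimum, so ties break deterministically.  Containment is
    closed on all four window edges.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    w, h = spec.width, spec.height
    if len(pts) == 0:
        return HotspotResult(
            slide_id=slide_id,
            method="window",
            region=_rect(0.0, 0.0, w, h),
            mc=0,
            region_area_mm2=w * h,
            tumor_id=tumor_id,
        )
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    xs = np.arange(xmin - w, xmax + _TOL, spec.stride_x)
    ys = np.arange(ymin - h, ymax + _TOL, spec.stride_y)
    # membership per axis, then counts for every grid cell at once
    in_x = (pts[None, :, 0] >= xs[:, None] - _TOL) & (
        pts[None, :, 0] <= xs[:, None] + w + _TOL
    )
    in_y = (pts[None, :, 1] >= ys[:, None] - _TOL) & (
        pts[None, :, 1] <= ys[:, None] + h + _TOL
    )
    counts = in_y.astype(np.int64) @ in_x.T.astype(np.int64)  # (len(ys), len(xs))
    iy, ix = np.unravel_index(int(np.argmax(counts)), counts.shape)
    region = _rect(float(xs[ix]), float(ys[iy]), w, h)
    return HotspotResult(
        slide_id=slide_id,
        method="window",
        region=region,
        mc=int(counts[iy, ix]),
        region_area_mm2=polygon_area(region.vertices),
        tumor_id=tumor_id,
    )


def window_oracle_mc(points, width: float, height: float, tol: float = _TOL) -> int:
    """Exact optimum of the fixed-window count, independent of any grid.

    A maximal axis-aligned window can always be translated until one enclosed
    point lies on its left edge and one on its top edge, so it suffices to
    scan windows anchored at every (x_i, y_j) pair of point coordinates.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return 0
    xs = np.unique(pts[:, 0])
    ys = np.unique(pts[:, 1])
    in_x = (pts[None, :, 0] >= xs[:, None] - tol) & (
        pts[None, :, 0] <= xs[:, None] + width + tol
    )
    in_y = (pts[None, :, 1] >= ys[:, None] - tol) & (
        pts[None, :, 1] <= ys[:, None] + height + tol
    )
    counts = in_y.astype(np.int64) @ in_x.T.astype(np.int64)
    return int(counts.max())
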