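"""Synthetic slides and paired cohorts with known ground truth.

A synthetic slide emulates what a mitosis detector emits on one whole-slide
image: clustered true mitotic figures (Thomas-process-like Gaussian hotspots
on top of a sparse homogeneous background, both confined to the tumor
polygon) plus false-positive candidates scattered inside and outside the
tumor.  Detection probabilities are drawn from two Beta distributions chosen
so that roughly 90% of true candidates score above the 0.64 operating point
and roughly 90% of false candidates score below it, so the probability filter
is exercised non-trivially.

Gaussian hotspots (rather than uniform discs) mirror the diffuse character of
mitotic hotspots in tissue and deliberately stress the convex-hull selector's
boundary decisions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .geometry import PolygonMM, ResolutionSpec, mm_to_px
from .io import DetectionCandidate, TumorAnnotation


def default_tumor_polygon(cx: float = 6.0, cy: float = 6.0, radius: float = 5.0) -> PolygonMM:
    """A regular octagon — a rough, convex-ish tumor outline of ~70 mm²."""
    ang = np.arange(8) * (2 * math.pi / 8) + math.pi / 8
    verts = np.column_stack([cx + radius * np.cos(ang), cy + radius * np.sin(ang)])
    return PolygonMM(verts)


@dataclass(frozen=True)
class Hotspot:
    center: tuple[float, float]  # mm
    sigma: float  # mm, isotropic Gaussian spread
    n_true: int

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_true < 0:
            raise ValueError("n_true must be non-negative")


@dataclass(frozen=True)
class SyntheticSlideSpec:
    """Generative description of one synthetic slide."""

    tumor_polygon: PolygonMM = field(default_factory=default_tumor_polygon)
    hotspots: tuple[Hotspot, ...] = (Hotspot(center=(6.0, 6.0), sigma=0.15, n_true=30),)
    background_rate: float = 0.5  # true MFs per mm² inside the tumor
    fp_rate_inside: float = 2.0  # false candidates per mm² inside the tumor
    fp_rate_outside: float = 1.0  # false candidates per mm² outside the tumor
    score_true: tuple[float, float] = (8.0, 2.0)  # Beta(a, b): 89% mass > 0.64
    score_false: tuple[float, float] = (1.0, 2.2)  # Beta(a, b): 89% mass < 0.64
    mpp: float = 0.23
    slide_id: str = "S1"
    case_id: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.background_rate, self.fp_rate_inside, self.fp_rate_outside) < 0:
            raise ValueError("rates must be non-negative")
        for h in self.hotspots:
            if not self.tumor_polygon.contains(*h.center):
                raise ValueError(f"hotspot center {h.center} outside the tumor polygon")


@dataclass(frozen=True)
class SyntheticTruth:
    """Planted ground truth for one generated slide."""

    hotspot_centers: np.ndarray  # (h, 2) mm
    n_true_per_hotspot: tuple[int, ...]
    labels: np.ndarray  # bool per emitted candidate: True = real mitotic figure
    planted_mc: int  # true MFs inside the default 2 mm² window at the densest center


_WINDOW_W = math.sqrt(2.0 * 4.0 / 3.0)  # default 2 mm², 4:3 hotspot window
_WINDOW_H = math.sqrt(2.0 * 3.0 / 4.0)


def _poisson_in_polygon(rng, poly: PolygonMM, rate: float) -> np.ndarray:
    """Homogeneous Poisson points inside a polygon, by rejection from the bbox."""
    if rate <= 0:
        return np.zeros((0, 2))
    n = rng.poisson(rate * poly.area)
    return _uniform_in_polygon(rng, poly, n)


def _uniform_in_polygon(rng, poly: PolygonMM, n: int) -> np.ndarray:
    if n == 0:
        return np.zeros((0, 2))
    minx, miny, maxx, maxy = poly.to_shapely().bounds
    out = []
    while len(out) < n:
        batch = max(4 * (n - len(out)), 16)
        cand = rng.uniform([minx, miny], [maxx, maxy], size=(batch, 2))
        keep = poly.contains_points(cand)
        out.extend(cand[keep].tolist())
    return np.asarray(out[:n])


def _gaussian_in_polygon(rng, poly: PolygonMM, center, sigma: float, n: int) -> np.ndarray:
    """Isotropic Gaussian cluster truncated to the polygon by resampling."""
    if n == 0:
        return np.zeros((0, 2))
    center = np.asarray(center, dtype=float)
    out: list[list[float]] = []
    tries = 0
    while len(out) < n:
        batch = max(4 * (n - len(out)), 16)
        cand = rng.normal(center, sigma, size=(batch, 2))
        keep = poly.contains_points(cand)
        out.extend(cand[keep].tolist())
        tries += 1
        if tries > 1000:
            raise RuntimeError("hotspot truncation failed; sigma too large for polygon?")
    return np.asarray(out[:n])


def _poisson_outside_polygon(rng, poly: PolygonMM, rate: float, margin: float = 2.0) -> np.ndarray:
    """Poisson points in the polygon's bounding box (expanded by ``margin`` mm)
    but outside the polygon — the stroma/artefact zone of a slide."""
    if rate <= 0:
        return np.zeros((0, 2))
    minx, miny, maxx, maxy = poly.to_shapely().bounds
    # slide coordinates are non-negative: clip the expanded box at the origin
    minx, miny = max(minx - margin, 0.0), max(miny - margin, 0.0)
    maxx, maxy = maxx + margin, maxy + margin
    box_area = (maxx - minx) * (maxy - miny)
    region_area = max(box_area - poly.area, 0.0)
    n = rng.poisson(rate * region_area)
    out: list[list[float]] = []
    while len(out) < n:
        batch = max(4 * (n - len(out)), 16)
        cand = rng.uniform([minx, miny], [maxx, maxy], size=(batch, 2))
        keep = ~poly.contains_points(cand)
        out.extend(cand[keep].tolist())
    return np.asarray(out[:n])


def generate_slide(
    spec: SyntheticSlideSpec,
) -> tuple[list[DetectionCandidate], TumorAnnotation, SyntheticTruth]:
    """Generate one slide's detection candidates, annotation and ground truth.

    Candidate order is fixed (background MFs, hotspot MFs in spec order, false
    positives inside, false positives outside) and the whole stream is a pure
    function of the seed.
    """
    rng = np.random.default_rng(spec.seed)
    poly = spec.tumor_polygon
    if len(poly.vertices) < 3:
        raise ValueError("tumor polygon is degenerate")

    bg = _poisson_in_polygon(rng, poly, spec.background_rate)
    hotspot_pts = [
        _gaussian_in_polygon(rng, poly, h.center, h.sigma, h.n_true)
        for h in spec.hotspots
    ]
    fp_in = _poisson_in_polygon(rng, poly, spec.fp_rate_inside)
    fp_out = _poisson_outside_polygon(rng, poly, spec.fp_rate_outside)

    true_pts = np.vstack([bg] + hotspot_pts) if hotspot_pts else bg
    false_pts = np.vstack([fp_in, fp_out])
    all_pts = np.vstack([true_pts, false_pts])
    labels = np.concatenate(
        [np.ones(len(true_pts), dtype=bool), np.zeros(len(false_pts), dtype=bool)]
    )

    at, bt = spec.score_true
    af, bf = spec.score_false
    scores = np.where(
        labels,
        stats.beta(at, bt).ppf(rng.uniform(size=len(all_pts))),
        stats.beta(af, bf).ppf(rng.uniform(size=len(all_pts))),
    )

    res = ResolutionSpec(spec.mpp)
    x_px, y_px = mm_to_px(all_pts[:, 0], all_pts[:, 1], res)
    candidates = [
        DetectionCandidate(
            candidate_id=f"{spec.slide_id}-c{i:05d}",
            slide_id=spec.slide_id,
            x_px=float(x_px[i]),
            y_px=float(y_px[i]),
            probability=float(np.clip(scores[i], 0.0, 1.0)),
            case_id=spec.case_id,
        )
        for i in range(len(all_pts))
    ]
    annot = TumorAnnotation(slide_id=spec.slide_id, polygons=(poly,))

    # planted MC: true MFs inside the default 2 mm² window centred on the
    # hotspot that captures the most of them
    planted = 0
    centers = np.array([h.center for h in spec.hotspots], dtype=float).reshape(-1, 2)
    for c in centers:
        lo = c - [_WINDOW_W / 2, _WINDOW_H / 2]
        hi = c + [_WINDOW_W / 2, _WINDOW_H / 2]
        inside = np.all((true_pts >= lo) & (true_pts <= hi), axis=1)
        planted = max(planted, int(inside.sum()))
    truth = SyntheticTruth(
        hotspot_centers=centers,
        n_true_per_hotspot=tuple(h.n_true for h in spec.hotspots),
        labels=labels,
        planted_mc=planted,
    )
    return candidates, annot, truth


def generate_paired_cohort(
    n_cases: int,
    rho: float,
    mc_distribution: dict | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Paired mitotic counts with a target latent correlation.

    Draws a latent bivariate normal with correlation ``rho`` and pushes both
    margins through the same monotone map (Gaussian CDF, then the quantile
    function of a negative binomial) so the counts have the right-skewed,
    many-low-some-high shape of clinical MC distributions.  ``rho = 1`` gives
    identical columns, hence Pearson r exactly 1.
    """
    if n_cases < 10:
        raise ValueError("need at least 10 cases")
    if not -1.0 <= rho <= 1.0:
        raise ValueError("rho must be in [-1, 1]")
    params = {"n": 3.0, "p": 3.0 / 11.0}  # mean 8, generously dispersed
    if mc_distribution:
        params.update(mc_distribution)
    rng = np.random.default_rng(seed)
    cov = np.array([[1.0, rho], [rho, 1.0]])
    # eigenvalue-clipped Cholesky-free sampling handles |rho| = 1 exactly
    z = rng.multivariate_normal([0.0, 0.0], cov, size=n_cases, method="eigh")
    u = stats.norm.cdf(z)
    counts = stats.nbinom(params["n"], params["p"]).ppf(u).astype(int)
    counts = np.maximum(counts, 0)
    return pd.DataFrame(
        {
            "case_id": [f"case{i:04d}" for i in range(n_cases)],
            "mc_a": counts[:, 0],
            "mc_b": counts[:, 1],
        }
    )
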