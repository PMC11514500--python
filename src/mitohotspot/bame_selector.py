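"""Bounded-area maximum-enclosing (BAME) convex hull hotspot selection.

The selector looks for the convex polygon of area at most the hotspot bound
(2 mm² by default) that encloses the most mitotic-figure detections.  Hull
vertices are restricted to detection points: any enclosing convex region can
be shrunk to the hull of the points it encloses without losing points or
gaining area, so the discrete search is complete.

The slide is subdivided into 4 mm² square patches overlapping by 0.5 mm.
Because a patch is only 2×2 mm, any within-patch hull that spans the patch
still has room for an average width of 0.5 mm before the 2 mm² bound bites,
which keeps selected hulls from degenerating into thin slivers.  Patches with
at most 25 points are solved exactly by branch and bound; larger patches use
a greedy growth heuristic.  The winning hull is recounted against all slide
points so detections assigned to a neighbouring overlapping patch are not
lost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .config import RunConfig
from .geometry import (
    EPS_AREA,
    PolygonMM,
    convex_hull,
    points_in_convex_polygon,
    polygon_area,
)
from .window_selector import HotspotResult

_AREA_TOL = 1e-9


@dataclass(frozen=True)
class PatchGrid:
    """Axis-aligned square patches tiling the detections' bounding box."""

    origins: np.ndarray  # (k, 2) top-left corners, row-major (y outer, x inner)
    side: float  # mm
    stride: float  # mm

    def __len__(self) -> int:
        return len(self.origins)


@dataclass(frozen=True)
class BameSolution:
    hull: np.ndarray  # (h, 2) CCW vertices, all of them input points
    enclosed_count: int
    area_mm2: float
    solver: str  # "exact", "heuristic" or "degenerate"


def _axis_starts(lo: float, hi: float, side: float, stride: float) -> list[float]:
    """Patch starts along one axis; the last start is clamped so no patch
    extends past the extent and the whole extent is covered."""
    if hi - lo <= side:
        return [lo]
    starts = []
    s = lo
    while s + side < hi - _AREA_TOL:
        starts.append(s)
        s += stride
    last = hi - side
    if not starts or last > starts[-1] + _AREA_TOL:
        starts.append(last)
    return starts


def build_patch_grid(points, cfg: RunConfig) -> PatchGrid:
    side = math.sqrt(cfg.patch_area_mm2)
    stride = side - cfg.patch_overlap_mm
    if stride <= 0:
        raise ValueError("patch overlap must be smaller than the patch side")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return PatchGrid(np.zeros((0, 2)), side, stride)
    xmin, ymin = pts.min(axis=0)
    xmax, ymax = pts.max(axis=0)
    xs = _axis_starts(xmin, xmax, side, stride)
    ys = _axis_starts(ymin, ymax, side, stride)
    origins = np.array([[x, y] for y in ys for x in xs])
    return PatchGrid(origins, side, stride)


def _dedupe(pts: np.ndarray):
    """Unique locations plus their multiplicities (two detections at the same
    coordinate count twice for MC but once for hull construction)."""
    uniq, counts = np.unique(pts, axis=0, return_counts=True)
    return uniq, counts


def _weighted_enclosed(hull: np.ndarray, uniq: np.ndarray, counts: np.ndarray) -> int:
    return int(counts[points_in_convex_polygon(hull, uniq)].sum())


def _best_degenerate(uniq: np.ndarray, counts: np.ndarray):
    """Best area-0 solution: a single location or a closed segment (with any
    collinear locations on it).  Always feasible for a positive area bound."""
    m = len(uniq)
    i0 = int(np.argmax(counts))
    best = (int(counts[i0]), uniq[i0 : i0 + 1].copy())
    if m >= 2:
        for i in range(m):
            for j in range(i + 1, m):
                seg = np.vstack([uniq[i], uniq[j]])
                w = _weighted_enclosed(seg, uniq, counts)
                if w > best[0]:
                    best = (w, seg)
    return best


def bame_exact(
    points, area_bound: float, *, max_points: int | None = None, eps: float = EPS_AREA
) -> BameSolution:
    """Optimal bounded-area maximum-enclosing convex hull.

    Branch and bound over convex-position vertex chains: every strictly convex
    polygon with vertices among the points is enumerated exactly once by its
    lowest vertex (the anchor, minimal (y, x)) followed by the remaining
    vertices in ascending angular order around it.  The fan decomposition from
    the anchor makes the area additive, so infeasible chains prune as soon as
    the bound is exceeded, and a suffix-weight bound on the points still ahead
    in angular order prunes chains that cannot beat the incumbent.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("bame_exact needs at least one point")
    if area_bound <= 0:
        raise ValueError("area bound must be positive")
    if max_points is not None and len(pts) > max_points:
        raise ValueError(
            f"{len(pts)} points exceed the exact-solver limit of {max_points}; "
            "use bame_heuristic"
        )
    n_total = len(pts)
    uniq, counts = _dedupe(pts)
    m = len(uniq)
    if m <= 2:
        return BameSolution(convex_hull(uniq), n_total, 0.0, "degenerate")
    full = convex_hull(uniq)
    full_area = polygon_area(full)
    if full_area <= area_bound + _AREA_TOL:
        return BameSolution(full, n_total, full_area, "exact")

    best_count, best_hull = _best_degenerate(uniq, counts)
    best_area = 0.0

    # anchors in ascending (y, x); candidate vertices must be strictly after
    order = np.lexsort((uniq[:, 0], uniq[:, 1]))
    for ai in range(m - 2):
        a = order[ai]
        va = uniq[a]
        cand_idx = order[ai + 1 :]
        d = uniq[cand_idx] - va
        ang = np.arctan2(d[:, 1], d[:, 0])  # dy >= 0 so angles lie in [0, pi]
        dist2 = (d**2).sum(axis=1)
        srt = np.lexsort((dist2, ang))
        cand_idx = cand_idx[srt]
        cp = uniq[cand_idx] - va  # candidate offsets from the anchor
        cw = counts[cand_idx].astype(np.int64)
        k = len(cand_idx)
        suffix = np.zeros(k + 1, dtype=np.int64)
        suffix[:k] = np.cumsum(cw[::-1])[::-1]
        base_w = int(counts[a])

        def in_tri(i: int, j: int) -> np.ndarray:
            """Closed containment of candidates in CCW triangle (anchor, i, j),
            in anchor-relative coordinates."""
            A, B = cp[i], cp[j]
            c1 = A[0] * cp[:, 1] - A[1] * cp[:, 0]  # left of anchor→A
            BA = B - A
            c2 = BA[0] * (cp[:, 1] - A[1]) - BA[1] * (cp[:, 0] - A[0])
            c3 = (-B[0]) * (cp[:, 1] - B[1]) + B[1] * (cp[:, 0] - B[0])
            return (c1 >= -eps) & (c2 >= -eps) & (c3 >= -eps)

        def dfs(chain: list[int], area: float, enclosed: np.ndarray) -> None:
            nonlocal best_count, best_hull, best_area
            last = chain[-1]
            if len(chain) >= 2:
                # closing turn at the last vertex must be convex
                pl, ll = cp[chain[-2]], cp[last]
                if (ll[0] - pl[0]) * (-ll[1]) - (ll[1] - pl[1]) * (-ll[0]) > eps:
                    hull = np.vstack([va, cp[chain] + va])
                    cnt = base_w + int(cw[enclosed].sum())
                    if cnt > best_count or (
                        cnt == best_count and area < best_area - _AREA_TOL
                    ):
                        best_count, best_hull, best_area = cnt, hull, area
            if base_w + int(suffix[last + 1]) + int(cw[enclosed].sum()) <= best_count:
                return
            for nxt in range(last + 1, k):
                # strictly counterclockwise from the anchor's view
                if cp[last, 0] * cp[nxt, 1] - cp[last, 1] * cp[nxt, 0] <= eps:
                    continue
                if len(chain) >= 2:
                    pl, ll, nn = cp[chain[-2]], cp[last], cp[nxt]
                    if (ll[0] - pl[0]) * (nn[1] - ll[1]) - (ll[1] - pl[1]) * (
                        nn[0] - ll[0]
                    ) <= eps:
                        continue  # reflex turn: not a convex chain
                tri = 0.5 * abs(cp[last, 0] * cp[nxt, 1] - cp[last, 1] * cp[nxt, 0])
                new_area = area + tri
                if new_area > area_bound + _AREA_TOL:
                    continue
                dfs(chain + [nxt], new_area, enclosed | in_tri(last, nxt))

        for first in range(k - 1):
            if base_w + int(suffix[first]) <= best_count:
                break  # later starts only see lighter suffixes
            # the chain so far is the closed segment anchor→first: mark the
            # segment's points so the prune bound never undercounts them
            F = cp[first]
            cross0 = F[0] * cp[:, 1] - F[1] * cp[:, 0]
            dot0 = cp @ F
            seg = (np.abs(cross0) <= eps) & (dot0 >= -eps) & (dot0 <= F @ F + eps)
            dfs([first], 0.0, seg)

    # recount with the standard predicate so boundary decisions are uniform
    final_count = _weighted_enclosed(best_hull, uniq, counts)
    return BameSolution(best_hull, final_count, polygon_area(best_hull), "exact")


def _monotone_chain_hull(sub: np.ndarray) -> np.ndarray:
    """Andrew's monotone chain (oracle-side hull, independent of gift wrap).
    ``sub`` must be lexicographically sorted by (x, y); returns CCW vertices."""
    n = len(sub)
    if n <= 2:
        return sub
    lower: list[int] = []
    for i in range(n):
        while len(lower) >= 2:
            o, a = sub[lower[-2]], sub[lower[-1]]
            if (a[0] - o[0]) * (sub[i, 1] - o[1]) - (a[1] - o[1]) * (
                sub[i, 0] - o[0]
            ) <= 0:
                lower.pop()
            else:
                break
        lower.append(i)
    upper: list[int] = []
    for i in range(n - 1, -1, -1):
        while len(upper) >= 2:
            o, a = sub[upper[-2]], sub[upper[-1]]
            if (a[0] - o[0]) * (sub[i, 1] - o[1]) - (a[1] - o[1]) * (
                sub[i, 0] - o[0]
            ) <= 0:
                upper.pop()
            else:
                break
        upper.append(i)
    return sub[lower[:-1] + upper[:-1]]


def bame_brute_force(points, area_bound: float) -> BameSolution:
    """Exhaustive-reference BAME solution for tiny instances (testing only).

    Enumerates every subset of distinct locations, takes its convex hull, and
    keeps the feasible hull enclosing the most points.  Exponential in the
    number of points; practical up to ~14 distinct locations.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("needs at least one point")
    n_total = len(pts)
    uniq, counts = _dedupe(pts)  # np.unique sorts rows lexicographically
    m = len(uniq)
    if m > 16:
        raise ValueError("brute force is limited to 16 distinct locations")
    if m <= 2:
        return BameSolution(convex_hull(uniq), n_total, 0.0, "degenerate")
    full = _monotone_chain_hull(uniq)
    if polygon_area(full) <= area_bound + _AREA_TOL:
        return BameSolution(full, n_total, polygon_area(full), "exact")
    best_count, best_hull = _best_degenerate(uniq, counts)
    best_area = 0.0
    idx = range(m)
    for size in range(3, m + 1):
        for comb in combinations(idx, size):
            sub = uniq[list(comb)]  # ascending comb keeps lexicographic order
            hull = _monotone_chain_hull(sub)
            area = polygon_area(hull)
            if area > area_bound + _AREA_TOL:
                continue
            cnt = _weighted_enclosed(hull, uniq, counts)
            if cnt > best_count or (cnt == best_count and area < best_area - _AREA_TOL):
                best_count, best_hull, best_area = cnt, hull, area
    return BameSolution(best_hull, best_count, polygon_area(best_hull), "exact")


def bame_heuristic(points, area_bound: float, seed: int = 0) -> BameSolution:
    """Greedy hull growth for patches too large for the exact solver.

    Seeds at the point of maximal local density (most detections within
    sqrt(area_bound)/2) and grows outward: each step adds the unenclosed
    point closest to the already-enclosed set whose inclusion keeps the
    gift-wrapped hull within the area bound (ties by lowest point index);
    growth stops when no feasible addition remains.  Proximity-first growth
    wraps the dense cluster before spending the area budget on long-range
    additions — both capture-greedy and smallest-area-increase rules fail on
    clustered data, the first by sweeping large triangles early, the second
    by chasing near-collinear far points whose thin slivers are almost free
    in area but elongate the hull past the cluster.  The procedure is
    deterministic — ``seed`` is part of the call signature so alternative
    stochastic strategies stay drop-in compatible.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        raise ValueError("bame_heuristic needs at least one point")
    if area_bound <= 0:
        raise ValueError("area bound must be positive")
    n_total = len(pts)
    uniq, counts = _dedupe(pts)
    m = len(uniq)
    if m <= 2:
        return BameSolution(convex_hull(uniq), n_total, 0.0, "degenerate")
    full = convex_hull(uniq)
    full_area = polygon_area(full)
    if full_area <= area_bound + _AREA_TOL:
        return BameSolution(full, n_total, full_area, "heuristic")

    r2 = area_bound / 4.0  # (sqrt(area)/2)^2 neighbourhood radius
    d2 = ((uniq[:, None, :] - uniq[None, :, :]) ** 2).sum(axis=2)
    density = (d2 <= r2 + _AREA_TOL) @ counts
    start = int(np.argmax(density))

    hull = uniq[start : start + 1].copy()
    enclosed = points_in_convex_polygon(hull, uniq)
    area = 0.0
    # squared distance from each location to the enclosed set (single linkage)
    near2 = d2[:, start].copy()
    while True:
        cand_order = sorted(
            (i for i in range(m) if not enclosed[i]), key=lambda i: (near2[i], i)
        )
        grown = False
        for i in cand_order:
            cand_hull = convex_hull(np.vstack([hull, uniq[i]]))
            cand_area = polygon_area(cand_hull)
            if cand_area > area_bound + _AREA_TOL:
                continue
            inside = points_in_convex_polygon(cand_hull, uniq)
            newly = inside & ~enclosed
            hull, area = cand_hull, cand_area
            enclosed |= inside
            near2 = np.minimum(near2, d2[:, newly].min(axis=1))
            grown = True
            break
        if not grown:
            break
    return BameSolution(hull, int(counts[enclosed].sum()), area, "heuristic")


def bame_select(
    points, cfg: RunConfig, *, slide_id: str = "", tumor_id: str | None = None
) -> HotspotResult:
    """Patch-dispatched BAME selection over a whole slide's detections.

    Each patch is solved exactly (≤ ``exact_solver_max_points`` points) or
    heuristically; every patch solution is then recounted against all slide
    points, since a hull near a patch border may enclose detections assigned
    to a neighbouring overlapping patch.  Ties across patches break by highest
    count, then smallest hull area, then lowest patch index.
    """
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return HotspotResult(
            slide_id=slide_id,
            method="bame",
            region=PolygonMM(np.zeros((1, 2))),
            mc=0,
            region_area_mm2=0.0,
            solver="degenerate",
            tumor_id=tumor_id,
        )
    grid = build_patch_grid(pts, cfg)
    side = grid.side
    best_key = None
    best = None
    for pi, (x0, y0) in enumerate(grid.origins):
        sel = (
            (pts[:, 0] >= x0 - _AREA_TOL)
            & (pts[:, 0] <= x0 + side + _AREA_TOL)
            & (pts[:, 1] >= y0 - _AREA_TOL)
            & (pts[:, 1] <= y0 + side + _AREA_TOL)
        )
        sub = pts[sel]
        if len(sub) == 0:
            continue
        if len(sub) <= cfg.exact_solver_max_points:
            sol = bame_exact(
                sub, cfg.hotspot_area_mm2, max_points=cfg.exact_solver_max_points
            )
        else:
            sol = bame_heuristic(sub, cfg.hotspot_area_mm2, cfg.random_seed)
        mc_all = int(np.sum(points_in_convex_polygon(sol.hull, pts)))
        key = (-mc_all, sol.area_mm2, pi)
        if best_key is None or key < best_key:
            best_key = key
            best = (sol, mc_all)
    sol, mc_all = best
    return HotspotResult(
        slide_id=slide_id,
        method="bame",
        region=PolygonMM(sol.hull),
        mc=mc_all,
        region_area_mm2=polygon_area(sol.hull),
        solver=sol.solver,
        tumor_id=tumor_id,
    )
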