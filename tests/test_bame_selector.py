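"""Bounded-area maximum-enclosing convex hull: patch grid, exact solver,
heuristic, slide-level dispatch."""

import math

import numpy as np
import pytest

from mitohotspot import (
    RunConfig,
    bame_brute_force,
    bame_exact,
    bame_heuristic,
    bame_select,
    build_patch_grid,
    convex_hull,
    polygon_area,
)
from mitohotspot.geometry import points_in_convex_polygon

from conftest import random_instance


class TestPatchGrid:
    def test_three_mm_span_clamps_last_start(self, cfg):
        pts = np.array([[0.0, 0.0], [3.0, 3.0]])
        grid = build_patch_grid(pts, cfg)
        assert grid.side == pytest.approx(2.0)
        assert grid.stride == pytest.approx(1.5)
        xs = sorted(set(grid.origins[:, 0]))
        assert xs == pytest.approx([0.0, 1.0])  # 1.5 clamped so the patch ends at 3.0
        assert len(grid) == 4

    def test_small_extent_single_patch(self, cfg):
        assert len(build_patch_grid(np.array([[0.0, 0.0], [1.9, 1.1]]), cfg)) == 1
        assert len(build_patch_grid(np.array([[5.0, 5.0]]), cfg)) == 1

    def test_every_point_covered(self, cfg):
        rng = np.random.default_rng(6)
        pts = rng.uniform(0, 13, size=(60, 2))
        grid = build_patch_grid(pts, cfg)
        for p in pts:
            assert any(
                (o[0] - 1e-9 <= p[0] <= o[0] + grid.side + 1e-9)
                and (o[1] - 1e-9 <= p[1] <= o[1] + grid.side + 1e-9)
                for o in grid.origins
            )


class TestExactSolver:
    def test_outlier_forces_exclusion(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1], [5, 5.0]])
        sol = bame_exact(pts, 2.0)
        assert sol.enclosed_count == 4
        assert sol.area_mm2 == pytest.approx(1.0)
        assert {tuple(v) for v in sol.hull} == {(0, 0), (1, 0), (1, 1), (0, 1)}

    def test_two_points_degenerate(self):
        sol = bame_exact(np.array([[0.0, 0.0], [1.0, 1.0]]), 2.0)
        assert (sol.enclosed_count, sol.area_mm2, sol.solver) == (2, 0.0, "degenerate")

    def test_feasible_full_hull_encloses_everything(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(0, 1, size=(10, 2))
        assert bame_exact(pts, 2.0).enclosed_count == 10

    def test_rejects_oversized_input(self):
        pts = np.random.default_rng(0).uniform(0, 1, size=(26, 2))
        with pytest.raises(ValueError, match="heuristic"):
            bame_exact(pts, 2.0, max_points=25)

    def test_duplicates_count_for_mc_not_for_vertices(self):
        pts = np.array([[0, 0], [0, 0], [1, 0], [1, 1], [0, 1], [9, 9.0]])
        sol = bame_exact(pts, 1.5)
        assert sol.enclosed_count == 5
        assert len(sol.hull) == 4

    def test_matches_subset_enumeration(self):
        for seed in range(150):
            pts, bound = random_instance(seed)
            a = bame_exact(pts, bound)
            b = bame_brute_force(pts, bound)
            assert a.enclosed_count == b.enclosed_count, seed
            assert a.area_mm2 <= bound + 1e-9

    def test_monotone_in_points(self):
        rng = np.random.default_rng(12)
        for _ in range(20):
            pts, bound = random_instance(int(rng.integers(1 << 30)), n_max=10)
            base = bame_exact(pts, bound).enclosed_count
            extra = np.vstack([pts, rng.uniform(0, 3, size=(1, 2))])
            assert bame_exact(extra, bound).enclosed_count >= base


class TestHeuristic:
    def test_tiny_instances_match_exact(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            pts = rng.uniform(0, 2, size=(3, 2))
            bound = float(rng.uniform(0.05, 2.0))
            assert (
                bame_heuristic(pts, bound).enclosed_count
                == bame_exact(pts, bound).enclosed_count
            )

    def test_feasible_full_hull_returns_all(self):
        pts = np.random.default_rng(14).uniform(0, 1, size=(40, 2))
        assert bame_heuristic(pts, 2.0).enclosed_count == 40

    def test_two_cluster_instance_keeps_dense_cluster(self):
        rng = np.random.default_rng(7)
        theta = rng.uniform(0, 2 * math.pi, 150)
        rad = 0.5 * np.sqrt(rng.uniform(0, 1, 150))
        dense = np.column_stack([5 + rad * np.cos(theta), 5 + rad * np.sin(theta)])
        sparse = rng.uniform(0, 10, size=(50, 2))
        sol = bame_heuristic(np.vstack([dense, sparse]), 2.0)
        assert sol.enclosed_count >= 150 * 0.95
        assert sol.area_mm2 <= 2.0 + 1e-9

    def test_never_beats_exact(self):
        for seed in range(60):
            pts, bound = random_instance(seed + 1000)
            h = bame_heuristic(pts, bound).enclosed_count
            e = bame_exact(pts, bound).enclosed_count
            assert h <= e
            if polygon_area(convex_hull(pts)) <= bound:
                assert h == e == len(pts)

    def test_unbounded_area_returns_everything(self):
        pts = np.random.default_rng(15).uniform(0, 50, size=(30, 2))
        assert bame_heuristic(pts, math.inf).enclosed_count == 30
        assert bame_exact(pts[:12], math.inf).enclosed_count == 12


class TestBameSelect:
    def test_single_dense_cluster(self, cfg):
        pts = np.random.default_rng(16).uniform(3, 4, size=(10, 2))
        hr = bame_select(pts, cfg)
        assert hr.mc == 10
        assert hr.method == "bame"

    def test_max_over_patch_clusters(self, cfg):
        rng = np.random.default_rng(17)
        a = rng.uniform(0, 0.5, size=(8, 2))
        b = 10 + rng.uniform(0, 0.5, size=(12, 2))
        hr = bame_select(np.vstack([a, b]), cfg)
        assert hr.mc == 12
        assert points_in_convex_polygon(hr.region.vertices, b).sum() == 12

    def test_large_patch_uses_heuristic_below_exact(self, cfg):
        rng = np.random.default_rng(18)
        pts = rng.uniform(0, 1.8, size=(30, 2))  # one patch, >25 points
        hr = bame_select(pts, RunConfig(hotspot_area_mm2=0.8))
        assert hr.solver == "heuristic"
        oracle = bame_exact(pts, 0.8).enclosed_count  # n=30 is still exact-solvable
        assert hr.mc <= oracle

    def test_empty_input(self, cfg):
        assert bame_select(np.zeros((0, 2)), cfg).mc == 0

    def test_hull_stays_within_patch_diameter(self, cfg):
        rng = np.random.default_rng(19)
        pts = rng.uniform(0, 9, size=(120, 2))
        hr = bame_select(pts, cfg)
        verts = hr.region.vertices
        diam = max(
            np.linalg.norm(verts[i] - verts[j])
            for i in range(len(verts))
            for j in range(i + 1, len(verts))
        ) if len(verts) > 1 else 0.0
        assert diam <= 2.0 * math.sqrt(2) + 1e-9
        assert hr.region_area_mm2 <= cfg.hotspot_area_mm2 + 1e-9
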