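"""Voronoi / Delaunay / MST / density features against geometric oracles."""

import itertools

import numpy as np
import pytest

from nucmorph import delaunay_features, density_features, mst_features, voronoi_features
from nucmorph.graphs import (
    GRAPH_FEATURE_NAMES,
    delaunay_edges,
    graph_feature_block,
    mst_edge_lengths,
    voronoi_cells,
)
from scipy.spatial import Delaunay


def grid_points(nx, ny, spacing, origin=0.0):
    xs = origin + spacing * np.arange(nx)
    ys = origin + spacing * np.arange(ny)
    return np.array([(x, y) for x in xs for y in ys], dtype=float)


class TestVoronoi:
    def test_regular_grid_cells_are_identical(self):
        pts = grid_points(6, 6, 10, origin=5.0)
        feats = voronoi_features(pts, (0, 0, 60, 60))
        assert feats["graph_voronoi_area_minmax_ratio"] == pytest.approx(1.0)
        assert feats["graph_voronoi_area_disorder"] == pytest.approx(0.0, abs=1e-9)

    def test_minmax_ratio_convention(self, rng):
        pts = rng.uniform(0, 100, size=(20, 2))
        feats = voronoi_features(pts, (0, 0, 100, 100))
        for q in ("area", "perimeter", "chord"):
            assert 0.0 < feats[f"graph_voronoi_{q}_minmax_ratio"] <= 1.0

    def test_cell_areas_match_shoelace_oracle(self, rng):
        pts = rng.uniform(0, 100, size=(20, 2))
        cells = voronoi_cells(pts, (0, 0, 100, 100))
        for cell in cells:
            v = np.asarray(cell.exterior.coords)[:-1]
            x, y = v[:, 0], v[:, 1]
            shoelace = 0.5 * abs(np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y))
            assert cell.area == pytest.approx(shoelace, abs=1e-9)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            voronoi_features(np.array([[0, 0], [1, 1], [2, 2], [3, 3]]), (0, 0, 5, 5))
        with pytest.raises(ValueError):
            voronoi_features(np.array([[0, 0], [1, 0], [0, 1]]), (0, 0, 5, 5))


class TestDelaunay:
    def test_unit_square_edge_multiset(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        feats = delaunay_features(pts)
        # edges {1,1,1,1,sqrt(2)} regardless of which diagonal is drawn
        assert feats["graph_delaunay_edge_length_mean"] == pytest.approx((4 + np.sqrt(2)) / 5)
        assert feats["graph_delaunay_edge_length_minmax_ratio"] == pytest.approx(1 / np.sqrt(2))

    def test_equilateral_lattice_has_zero_area_disorder(self):
        # triangular lattice: every Delaunay triangle congruent
        pts = []
        for j in range(5):
            for i in range(5):
                pts.append((i + 0.5 * (j % 2), j * np.sqrt(3) / 2))
        feats = delaunay_features(np.array(pts))
        assert feats["graph_delaunay_tri_area_disorder"] == pytest.approx(0.0, abs=1e-9)

    def test_empty_circumcircle_property(self, rng):
        pts = rng.uniform(0, 50, size=(30, 2))
        tri = Delaunay(pts)
        for simplex in tri.simplices:
            a, b, c = pts[simplex]
            # circumcenter via perpendicular bisector intersection
            d = 2 * (a[0] * (b[1] - c[1]) + b[0] * (c[1] - a[1]) + c[0] * (a[1] - b[1]))
            ux = ((a @ a) * (b[1] - c[1]) + (b @ b) * (c[1] - a[1]) + (c @ c) * (a[1] - b[1])) / d
            uy = ((a @ a) * (c[0] - b[0]) + (b @ b) * (a[0] - c[0]) + (c @ c) * (b[0] - a[0])) / d
            center = np.array([ux, uy])
            radius = np.linalg.norm(a - center)
            dists = np.linalg.norm(pts - center, axis=1)
            inside = np.sum(dists < radius - 1e-9)
            assert inside == 0


class TestMST:
    def test_unit_square_tree(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], dtype=float)
        feats = mst_features(pts)
        assert mst_edge_lengths(pts).sum() == pytest.approx(3.0)
        assert feats["graph_mst_edge_sd"] == pytest.approx(0.0)
        assert feats["graph_mst_edge_minmax_ratio"] == pytest.approx(1.0)

    def test_collinear_points(self):
        pts = np.array([[0, 0], [1, 0], [2, 0], [3, 0]], dtype=float)
        assert mst_features(pts)["graph_mst_edge_mean"] == pytest.approx(1.0)

    def test_matches_exhaustive_spanning_tree_enumeration(self, rng):
        """MST weight equals the minimum over all labeled spanning trees
        (Pruefer-sequence enumeration, n <= 6)."""
        for _ in range(3):
            n = 6
            pts = rng.uniform(0, 10, size=(n, 2))
            dm = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
            best = np.inf
            for pruefer in itertools.product(range(n), repeat=n - 2):
                degree = [1] * n
                for v in pruefer:
                    degree[v] += 1
                seq = list(pruefer)
                weight = 0.0
                deg = degree[:]
                ptr = [v for v in range(n) if deg[v] == 1]
                import heapq

                heapq.heapify(ptr)
                for v in seq:
                    leaf = heapq.heappop(ptr)
                    weight += dm[leaf, v]
                    deg[v] -= 1
                    if deg[v] == 1:
                        heapq.heappush(ptr, v)
                u, w = heapq.heappop(ptr), heapq.heappop(ptr)
                weight += dm[u, w]
                best = min(best, weight)
            assert mst_edge_lengths(pts).sum() == pytest.approx(best, abs=1e-9)

    def test_single_point_rejected(self):
        with pytest.raises(ValueError):
            mst_features(np.array([[0.0, 0.0]]))


class TestDensity:
    def test_two_tight_clusters(self, rng):
        a = rng.uniform(0, 30, size=(10, 2))
        b = rng.uniform(0, 30, size=(10, 2)) + [300, 0]
        feats = density_features(np.vstack([a, b]), (0, 0, 400, 100))
        # every intra-cluster distance < 50, clusters 300 px apart
        assert feats["graph_density_r50_mean"] == pytest.approx(9.0)

    def test_sparse_grid_has_zero_r50_counts(self):
        pts = grid_points(4, 4, 60)
        feats = density_features(pts, (0, 0, 200, 200))
        assert feats["graph_density_r50_mean"] == 0.0

    def test_knn_distances_match_bruteforce(self, rng):
        pts = rng.uniform(0, 100, size=(50, 2))
        feats = density_features(pts, (0, 0, 100, 100))
        dm = np.linalg.norm(pts[:, None] - pts[None, :], axis=2)
        for k in (3, 5, 7):
            expected = np.sort(dm, axis=1)[:, k]  # column 0 is self
            assert feats[f"graph_knn_k{k}_mean"] == pytest.approx(expected.mean())
            assert feats[f"graph_knn_k{k}_sd"] == pytest.approx(expected.std())

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            density_features(np.zeros((5, 2)), (0, 0, 10, 10))


class TestBlock:
    def test_cardinality_and_unique_names(self):
        assert len(GRAPH_FEATURE_NAMES) == 51
        assert len(set(GRAPH_FEATURE_NAMES)) == 51

    def test_translation_invariance(self, rng):
        pts = rng.uniform(10, 90, size=(40, 2))
        a = graph_feature_block(pts, (0, 0, 100, 100))
        b = graph_feature_block(pts + [37.0, -11.0], (37.0, -11.0, 137.0, 89.0))
        for name in GRAPH_FEATURE_NAMES:
            assert a[name] == pytest.approx(b[name], rel=1e-9, abs=1e-9), name

    def test_scaling_behavior_of_geometric_groups(self, rng):
        """Under uniform scaling, means/sds of the tessellation groups
        scale by the right power while ratios and disorders are invariant."""
        pts = rng.uniform(10, 90, size=(40, 2))
        a = graph_feature_block(pts, (0, 0, 100, 100))
        b = graph_feature_block(pts * 2.0, (0, 0, 200, 200))
        assert b["graph_mst_edge_mean"] == pytest.approx(2 * a["graph_mst_edge_mean"])
        assert b["graph_delaunay_tri_area_mean"] == pytest.approx(
            4 * a["graph_delaunay_tri_area_mean"]
        )
        for name in GRAPH_FEATURE_NAMES:
            if name.endswith(("minmax_ratio", "disorder")) and "density" not in name \
                    and "knn" not in name and "window" not in name:
                assert a[name] == pytest.approx(b[name], rel=1e-9, abs=1e-9), name
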