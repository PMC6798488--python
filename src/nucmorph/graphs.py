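"""Global spatial-arrangement features from nucleus centroids.

51 features in four groups computed on the centroid point pattern of a
tissue image:

* **Voronoi** (12): cell area, perimeter and chord-length statistics over
  cells clipped to the field rectangle (boundary nuclei kept).  Chord
  lengths are all vertex-to-vertex segment lengths of the cell polygon
  (edges plus diagonals).
* **Delaunay** (8): triangle-area and edge-length statistics.
* **MST** (4): Euclidean minimum-spanning-tree edge-length statistics.
* **Density** (27): neighbor counts within radii 10..50 px, distances to
  the 3rd/5th/7th nearest neighbor, and counts in sliding 100 px windows
  (stride 50).

Each group reports the {mean, sd, min/max ratio, disorder} summary per
base quantity (density rows use {mean, sd, disorder}).
"""

from __future__ import annotations

import numpy as np
from scipy.sparse.csgraph import minimum_spanning_tree
from scipy.spatial import Delaunay, Voronoi, cKDTree, distance_matrix
from shapely.geometry import Polygon, box

from ._stats import disorder, summary4

__all__ = [
    "voronoi_cells",
    "voronoi_features",
    "delaunay_features",
    "mst_edge_lengths",
    "mst_features",
    "density_features",
    "graph_feature_block",
    "GRAPH_FEATURE_NAMES",
]

DENSITY_RADII = (10, 20, 30, 40, 50)
KNN_KS = (3, 5, 7)
WINDOW_SIDE = 100
WINDOW_STRIDE = 50

_S4 = ("mean", "sd", "minmax_ratio", "disorder")
_S3 = ("mean", "sd", "disorder")

GRAPH_FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"graph_voronoi_{q}_{s}" for q in ("area", "perimeter", "chord") for s in _S4]
    + [f"graph_delaunay_{q}_{s}" for q in ("tri_area", "edge_length") for s in _S4]
    + [f"graph_mst_edge_{s}" for s in _S4]
    + [f"graph_density_r{r}_{s}" for r in DENSITY_RADII for s in _S3]
    + [f"graph_knn_k{k}_{s}" for k in KNN_KS for s in _S3]
    + [f"graph_window_density_{s}" for s in _S3]
)
assert len(GRAPH_FEATURE_NAMES) == 51


def _validate_points(points: np.ndarray, minimum: int) -> np.ndarray:
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ValueError("points must be an (n, 2) array")
    if len(pts) < minimum:
        raise ValueError(f"need at least {minimum} points, got {len(pts)}")
    return pts


def _check_noncollinear(pts: np.ndarray) -> None:
    centered = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centered, tol=1e-9) < 2:
        raise ValueError("points are collinear (degenerate geometry)")


def voronoi_cells(
    points: np.ndarray, bounds: tuple[float, float, float, float]
) -> list[Polygon]:
    """Voronoi cell polygons clipped to the field rectangle.

    Unbounded cells are made finite by mirroring the point set across the
    four sides of ``bounds`` before tessellating; every original point
    then owns a bounded cell, which is clipped to the rectangle.
    ``bounds`` is (xmin, ymin, xmax, ymax).
    """
    pts = _validate_points(points, 4)
    _check_noncollinear(pts)
    xmin, ymin, xmax, ymax = bounds
    mirrored = [pts]
    for refl in (
        np.array([[2 * xmin, 0.0]]) + pts * [-1, 1],
        np.array([[2 * xmax, 0.0]]) + pts * [-1, 1],
        np.array([[0.0, 2 * ymin]]) + pts * [1, -1],
        np.array([[0.0, 2 * ymax]]) + pts * [1, -1],
    ):
        mirrored.append(refl)
    vor = Voronoi(np.vstack(mirrored))
    field = box(xmin, ymin, xmax, ymax)
    cells: list[Polygon] = []
    for i in range(len(pts)):
        region = vor.regions[vor.point_region[i]]
        if -1 in region or len(region) < 3:
            continue  # cannot happen after mirroring, kept as a guard
        poly = Polygon(vor.vertices[region]).intersection(field)
        if not poly.is_empty and poly.geom_type == "Polygon" and poly.area > 0:
            cells.append(poly)
    if not cells:
        raise ValueError("no valid Voronoi cells (degenerate geometry)")
    return cells


def voronoi_features(
    points: np.ndarray, bounds: tuple[float, float, float, float]
) -> dict[str, float]:
    """12 Voronoi statistics: {area, perimeter, chord} x summary4."""
    cells = voronoi_cells(points, bounds)
    areas = np.array([c.area for c in cells])
    perims = np.array([c.length for c in cells])
    chords = []
    for c in cells:
        verts = np.asarray(c.exterior.coords)[:-1]
        d = distance_matrix(verts, verts)
        chords.extend(d[np.triu_indices(len(verts), k=1)])
    chords = np.asarray(chords)
    out: dict[str, float] = {}
    for q, vals in (("area", areas), ("perimeter", perims), ("chord", chords)):
        for s, v in summary4(vals).items():
            out[f"graph_voronoi_{q}_{s}"] = v
    return out


def _delaunay(points: np.ndarray) -> Delaunay:
    pts = _validate_points(points, 4)
    _check_noncollinear(pts)
    return Delaunay(pts)


def delaunay_edges(tri: Delaunay) -> np.ndarray:
    """Unique undirected edges (m, 2) of a Delaunay triangulation."""
    edges = set()
    for simplex in tri.simplices:
        for a, b in ((0, 1), (1, 2), (0, 2)):
            edges.add(tuple(sorted((simplex[a], simplex[b]))))
    return np.array(sorted(edges))


def delaunay_features(points: np.ndarray) -> dict[str, float]:
    """8 Delaunay statistics: {triangle area, edge length} x summary4."""
    tri = _delaunay(points)
    pts = tri.points
    a, b, c = (pts[tri.simplices[:, k]] for k in range(3))
    ab, ac = b - a, c - a
    tri_areas = 0.5 * np.abs(ab[:, 0] * ac[:, 1] - ab[:, 1] * ac[:, 0])
    edges = delaunay_edges(tri)
    lengths = np.linalg.norm(pts[edges[:, 0]] - pts[edges[:, 1]], axis=1)
    out: dict[str, float] = {}
    for q, vals in (("tri_area", tri_areas), ("edge_length", lengths)):
        for s, v in summary4(vals).items():
            out[f"graph_delaunay_{q}_{s}"] = v
    return out


def mst_edge_lengths(points: np.ndarray) -> np.ndarray:
    """Edge lengths of the Euclidean minimum spanning tree."""
    pts = _validate_points(points, 2)
    dm = distance_matrix(pts, pts)
    mst = minimum_spanning_tree(dm)
    return np.asarray(mst[mst.nonzero()]).ravel()


def mst_features(points: np.ndarray) -> dict[str, float]:
    """4 MST edge-length statistics (summary4)."""
    lengths = mst_edge_lengths(points)
    return {f"graph_mst_edge_{s}": v for s, v in summary4(lengths).items()}


def density_features(
    points: np.ndarray, bounds: tuple[float, float, float, float]
) -> dict[str, float]:
    """27 neighborhood-density statistics.

    Per nucleus: neighbor counts within each radius in ``DENSITY_RADII``
    and distance to the k-th nearest neighbor for k in ``KNN_KS``; plus
    counts in square windows of side 100 px slid at stride 50 over the
    field.  Each quantity is summarized by {mean, sd, disorder}.
    """
    pts = _validate_points(points, 8)
    if len(pts) < max(KNN_KS) + 1:
        raise ValueError(f"need at least {max(KNN_KS) + 1} points")
    tree = cKDTree(pts)
    out: dict[str, float] = {}
    for r in DENSITY_RADII:
        counts = np.array([len(tree.query_ball_point(p, r)) - 1 for p in pts], dtype=float)
        out[f"graph_density_r{r}_mean"] = float(counts.mean())
        out[f"graph_density_r{r}_sd"] = float(counts.std())
        out[f"graph_density_r{r}_disorder"] = disorder(counts)
    dists, _ = tree.query(pts, k=max(KNN_KS) + 1)
    for k in KNN_KS:
        dk = dists[:, k]
        out[f"graph_knn_k{k}_mean"] = float(dk.mean())
        out[f"graph_knn_k{k}_sd"] = float(dk.std())
        out[f"graph_knn_k{k}_disorder"] = disorder(dk)
    xmin, ymin, xmax, ymax = bounds
    xs = np.arange(xmin, max(xmax - WINDOW_SIDE, xmin) + 1e-9, WINDOW_STRIDE)
    ys = np.arange(ymin, max(ymax - WINDOW_SIDE, ymin) + 1e-9, WINDOW_STRIDE)
    win_counts = []
    for x0 in xs:
        for y0 in ys:
            inside = (
                (pts[:, 0] >= x0)
                & (pts[:, 0] < x0 + WINDOW_SIDE)
                & (pts[:, 1] >= y0)
                & (pts[:, 1] < y0 + WINDOW_SIDE)
            )
            win_counts.append(inside.sum())
    win_counts = np.asarray(win_counts, dtype=float)
    out["graph_window_density_mean"] = float(win_counts.mean())
    out["graph_window_density_sd"] = float(win_counts.std())
    out["graph_window_density_disorder"] = disorder(win_counts)
    return out


def graph_feature_block(
    points: np.ndarray, bounds: tuple[float, float, float, float]
) -> dict[str, float]:
    """All 51 global-graph features in roster order."""
    out: dict[str, float] = {}
    out.update(voronoi_features(points, bounds))
    out.update(delaunay_features(points))
    out.update(mst_features(points))
    out.update(density_features(points, bounds))
    return {name: out[name] for name in GRAPH_FEATURE_NAMES}
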