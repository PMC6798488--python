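"""Cell Cluster Graph (CCG) construction and local-connectivity features.

The CCG links nearby nuclei with a distance-decaying rule made
deterministic: an edge (u, v) exists iff d(u, v)^(-alpha) >= r, i.e.
d(u, v) <= r^(-1/alpha).  With the defaults alpha = 0.5, r = 0.2 the edge
threshold is 25 px at x20 magnification.  25 subgraph-connectivity
statistics summarize the local clustering of nuclei.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import kurtosis, skew

from ._stats import disorder, minmax_ratio

__all__ = ["CellClusterGraph", "build_ccg", "ccg_feature_block", "CCG_FEATURE_NAMES"]

ALPHA_DEFAULT = 0.5
R_DEFAULT = 0.2

CCG_FEATURE_NAMES: tuple[str, ...] = (
    "ccg_n_nodes",
    "ccg_n_edges",
    "ccg_avg_degree",
    "ccg_avg_edge_density",
    "ccg_n_components",
    "ccg_giant_ratio",
    "ccg_avg_component_size",
    "ccg_pct_isolated",
    "ccg_pct_end_points",
    "ccg_pct_central_points",
    "ccg_avg_eccentricity",
    "ccg_diameter",
    "ccg_radius",
    "ccg_eccentricity_p90",
    "ccg_diameter_p90",
    "ccg_radius_p90",
    "ccg_avg_path_length",
    "ccg_avg_clustering_coeff",
    "ccg_transitivity",
    "ccg_edge_length_mean",
    "ccg_edge_length_sd",
    "ccg_edge_length_minmax_ratio",
    "ccg_edge_length_disorder",
    "ccg_edge_length_skewness",
    "ccg_edge_length_kurtosis",
)
assert len(CCG_FEATURE_NAMES) == 25


@dataclass
class CellClusterGraph:
    graph: nx.Graph  # nodes carry 'pos'; edges carry 'length'
    alpha: float
    r: float

    @property
    def threshold(self) -> float:
        return self.r ** (-1.0 / self.alpha)


def build_ccg(
    points: np.ndarray, alpha: float = ALPHA_DEFAULT, r: float = R_DEFAULT
) -> CellClusterGraph:
    """Deterministic CCG: edge iff centroid distance <= r^(-1/alpha)."""
    if alpha <= 0:
        raise ValueError("alpha must be > 0")
    if not 0.0 < r < 1.0:
        raise ValueError("r must be in (0, 1)")
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or len(pts) < 1:
        raise ValueError("points must be a non-empty (n, 2) array")
    threshold = r ** (-1.0 / alpha)
    g = nx.Graph()
    for i, p in enumerate(pts):
        g.add_node(i, pos=(float(p[0]), float(p[1])))
    tree = cKDTree(pts)
    for i, j in tree.query_pairs(threshold):
        g.add_edge(int(i), int(j), length=float(np.linalg.norm(pts[i] - pts[j])))
    return CellClusterGraph(graph=g, alpha=alpha, r=r)


def ccg_feature_block(ccg: CellClusterGraph) -> dict[str, float]:
    """The 25 CCG connectivity statistics.

    Path-based statistics (eccentricity, diameter, radius, shortest-path
    length) are computed per connected component of >= 2 nodes and
    averaged weighted by component size; isolated nodes are excluded from
    them.  Percentages are over all nodes.  Degenerate conventions: with
    no edges all edge-length statistics are 0; skewness/kurtosis are 0
    with fewer than 3 edges.
    """
    g = ccg.graph
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("empty graph")
    m = g.number_of_edges()
    degrees = np.array([d for _, d in g.degree()], dtype=float)

    components = [g.subgraph(c) for c in nx.connected_components(g)]
    comp_sizes = np.array([c.number_of_nodes() for c in components], dtype=float)
    big = [c for c in components if c.number_of_nodes() >= 2]

    densities = [
        c.number_of_edges() / (c.number_of_nodes() * (c.number_of_nodes() - 1) / 2)
        for c in big
    ]
    avg_density = float(np.mean(densities)) if densities else 0.0

    ecc_all: list[float] = []
    central = 0
    path_lengths: list[float] = []  # per-component average, size-weighted
    path_weights: list[float] = []
    pair_dists: list[int] = []
    for c in big:
        ecc = nx.eccentricity(c)
        comp_radius = min(ecc.values())
        ecc_all.extend(ecc.values())
        central += sum(1 for e in ecc.values() if e == comp_radius)
        apl = nx.average_shortest_path_length(c)
        path_lengths.append(apl)
        path_weights.append(c.number_of_nodes())
        for _, dists in nx.all_pairs_shortest_path_length(c):
            pair_dists.extend(d for d in dists.values() if d > 0)

    ecc_arr = np.asarray(ecc_all, dtype=float)
    if ecc_arr.size:
        avg_ecc = float(ecc_arr.mean())
        diameter = float(ecc_arr.max())
        radius = float(ecc_arr.min())
        ecc_p90 = float(np.percentile(ecc_arr, 90))
        radius_p90 = float(np.percentile(ecc_arr, 10))
    else:
        avg_ecc = diameter = radius = ecc_p90 = radius_p90 = 0.0
    diameter_p90 = float(np.percentile(pair_dists, 90)) if pair_dists else 0.0
    avg_path = (
        float(np.average(path_lengths, weights=path_weights)) if path_lengths else 0.0
    )

    lengths = np.array([d["length"] for _, _, d in g.edges(data=True)], dtype=float)
    if lengths.size:
        el_mean = float(lengths.mean())
        el_sd = float(lengths.std())
        el_ratio = minmax_ratio(lengths)
        el_dis = disorder(lengths)
        el_skew = float(skew(lengths, bias=False)) if lengths.size >= 3 else 0.0
        el_kurt = float(kurtosis(lengths, bias=False)) if lengths.size >= 4 else 0.0
        if not np.isfinite(el_skew):  # constant lengths
            el_skew = 0.0
        if not np.isfinite(el_kurt):
            el_kurt = 0.0
    else:
        el_mean = el_sd = el_skew = el_kurt = el_dis = 0.0
        el_ratio = 0.0

    return {
        "ccg_n_nodes": float(n),
        "ccg_n_edges": float(m),
        "ccg_avg_degree": float(degrees.mean()),
        "ccg_avg_edge_density": avg_density,
        "ccg_n_components": float(len(components)),
        "ccg_giant_ratio": float(comp_sizes.max() / n),
        "ccg_avg_component_size": float(comp_sizes.mean()),
        "ccg_pct_isolated": float(100.0 * np.sum(comp_sizes == 1) / n),
        "ccg_pct_end_points": float(100.0 * np.sum(degrees == 1) / n),
        "ccg_pct_central_points": float(100.0 * central / n),
        "ccg_avg_eccentricity": avg_ecc,
        "ccg_diameter": diameter,
        "ccg_radius": radius,
        "ccg_eccentricity_p90": ecc_p90,
        "ccg_diameter_p90": diameter_p90,
        "ccg_radius_p90": radius_p90,
        "ccg_avg_path_length": avg_path,
        "ccg_avg_clustering_coeff": float(nx.average_clustering(g)) if n else 0.0,
        "ccg_transitivity": float(nx.transitivity(g)),
        "ccg_edge_length_mean": el_mean,
        "ccg_edge_length_sd": el_sd,
        "ccg_edge_length_minmax_ratio": el_ratio,
        "ccg_edge_length_disorder": el_dis,
        "ccg_edge_length_skewness": el_skew,
        "ccg_edge_length_kurtosis": el_kurt,
    }
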