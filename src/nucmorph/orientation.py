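"""Cell Orientation Entropy (CORE): second-order statistics of nuclear
orientation co-occurrence among neighboring nuclei.

Nuclear major-axis orientations (axial, [0, 180°)) are quantized into B
equal bins.  For each nucleus with at least two CCG neighbors, a B x B
co-occurrence matrix counts quantized-orientation pairs over all
unordered pairs in its *closed* CCG neighborhood (the nucleus plus its
neighbors), symmetrized and normalized.  The 13 Haralick-family
statistics of each matrix are aggregated across nuclei by
{mean, sd, range}, giving 39 features.  Loss of nuclear polarity
(orientation disorder) raises the entropy-type statistics.
"""

from __future__ import annotations

import warnings

import numpy as np

from ._stats import HARALICK_STAT_NAMES, haralick_stats
from .ccg import CellClusterGraph

__all__ = [
    "build_orientation_cooccurrence",
    "second_order_stats",
    "core_feature_block",
    "CORE_FEATURE_NAMES",
    "BIN_COUNT_DEFAULT",
]

BIN_COUNT_DEFAULT = 10  # 18-degree bins

_AGGS = ("mean", "sd", "range")
CORE_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"core_{agg}_{stat}" for agg in _AGGS for stat in HARALICK_STAT_NAMES
)
assert len(CORE_FEATURE_NAMES) == 39


def quantize_orientations(orientations: np.ndarray, b: int) -> np.ndarray:
    """Bin axial orientations [0, 180) into b equal bins."""
    ori = np.asarray(orientations, dtype=float)
    if np.any((ori < 0) | (ori >= 180.0)):
        raise ValueError("orientations must lie in [0, 180)")
    return np.minimum((ori / (180.0 / b)).astype(int), b - 1)


def build_orientation_cooccurrence(
    orientations: np.ndarray, graph: CellClusterGraph, b: int = BIN_COUNT_DEFAULT
) -> list[np.ndarray]:
    """Per-nucleus symmetric, normalized orientation co-occurrence matrices.

    One matrix per nucleus having >= 2 CCG neighbors; pairs are all
    unordered pairs within the closed neighborhood.
    """
    if b < 2:
        raise ValueError("bin count must be >= 2")
    bins = quantize_orientations(orientations, b)
    g = graph.graph
    matrices: list[np.ndarray] = []
    for node in g.nodes:
        neigh = list(g.neighbors(node))
        if len(neigh) < 2:
            continue
        members = [node] + neigh
        mat = np.zeros((b, b))
        for a_i in range(len(members)):
            for a_j in range(a_i + 1, len(members)):
                bi, bj = bins[members[a_i]], bins[members[a_j]]
                mat[bi, bj] += 1.0
                mat[bj, bi] += 1.0
        mat /= mat.sum()
        matrices.append(mat)
    return matrices


def second_order_stats(m: np.ndarray) -> dict[str, float]:
    """13 Haralick-family statistics of one normalized co-occurrence matrix."""
    return haralick_stats(m)


def core_feature_block(
    orientations: np.ndarray,
    graph: CellClusterGraph,
    b: int = BIN_COUNT_DEFAULT,
) -> dict[str, float]:
    """The 39 CORE features: 13 statistics x {mean, sd, range} aggregates.

    If no nucleus has >= 2 neighbors, an all-zero block is returned with a
    warning (a field too sparse for orientation co-occurrence).
    """
    matrices = build_orientation_cooccurrence(orientations, graph, b)
    if not matrices:
        warnings.warn(
            "no nucleus with >= 2 CCG neighbors; CORE block is all zeros",
            stacklevel=2,
        )
        return {name: 0.0 for name in CORE_FEATURE_NAMES}
    rows = np.array(
        [[haralick_stats(m)[stat] for stat in HARALICK_STAT_NAMES] for m in matrices]
    )
    out: dict[str, float] = {}
    for j, stat in enumerate(HARALICK_STAT_NAMES):
        col = rows[:, j]
        out[f"core_mean_{stat}"] = float(col.mean())
        out[f"core_sd_{stat}"] = float(col.std())
        out[f"core_range_{stat}"] = float(col.max() - col.min())
    return {name: out[name] for name in CORE_FEATURE_NAMES}
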