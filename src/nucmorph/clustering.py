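"""PCA projection and resampled consensus hierarchical clustering.

Patients are projected onto the top two principal components of the
z-scored feature table, then clustered into two groups by consensus over
50 agglomerative (average-linkage) clusterings of 80% patient resamples.
The consensus matrix entry for a pair is the fraction of co-sampled runs
in which the pair landed in the same cluster; the final 2-cluster cut is
an average-linkage clustering of (1 - consensus).

The default pairwise distance on the 2-D score profiles is Euclidean: a
centered Pearson-correlation distance of 2-vectors degenerates to the
two values {0, 2} and carries no geometry, so the correlation option is
kept only as an explicit flag (``distance='pearson'``) for
higher-dimensional profiles.

A named six-feature image signature (orientation-entropy mean
information measure 1; CCG edge-length skewness and average component
size; Voronoi chord min/max ratio, polygon-area sd and polygon-area
min/max ratio) can be clustered directly instead of PC scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.decomposition import PCA

__all__ = [
    "SIGNATURE_FEATURES",
    "pca_top2",
    "ConsensusCluster",
    "consensus_cluster",
    "ConsensusResult",
    "cross_tabulate",
]

SIGNATURE_FEATURES: tuple[str, ...] = (
    "core_mean_info_measure1",
    "ccg_edge_length_skewness",
    "graph_voronoi_chord_minmax_ratio",
    "graph_voronoi_area_sd",
    "graph_voronoi_area_minmax_ratio",
    "ccg_avg_component_size",
)


def pca_top2(X) -> np.ndarray:
    """Scores on the top two principal components of the z-scored table.

    Constant columns are dropped with a warning; component signs are
    fixed so the loading of largest magnitude is positive.
    """
    import warnings

    if isinstance(X, pd.DataFrame):
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
    if len(Xv) < 3:
        raise ValueError("need >= 3 patients")
    sd = Xv.std(axis=0)
    keep = sd > 0
    if not np.all(keep):
        warnings.warn(f"dropping {np.sum(~keep)} constant column(s)", stacklevel=2)
    Xv = Xv[:, keep]
    if Xv.shape[1] < 2:
        raise ValueError("need >= 2 non-constant features")
    Z = (Xv - Xv.mean(axis=0)) / Xv.std(axis=0)
    pca = PCA(n_components=2, svd_solver="full")
    scores = pca.fit_transform(Z)
    for k in range(2):
        load = pca.components_[k]
        if load[np.argmax(np.abs(load))] < 0:
            scores[:, k] = -scores[:, k]
    return scores


@dataclass
class ConsensusResult:
    consensus_matrix: np.ndarray
    assignments: np.ndarray  # cluster index in {1, 2}
    n_runs: int
    resample_rate: float


def _pair_dist(scores: np.ndarray, distance: str) -> np.ndarray:
    if distance == "euclidean":
        return pdist(scores)
    if distance == "pearson":
        return pdist(scores, metric="correlation")
    raise ValueError("distance must be 'euclidean' or 'pearson'")


def consensus_cluster(
    scores: np.ndarray,
    k: int = 2,
    n_runs: int = 50,
    resample_rate: float = 0.8,
    seed: int = 0,
    distance: str = "euclidean",
    linkage_method: str = "average",
) -> ConsensusResult:
    """Resampled consensus agglomerative clustering into k=2 groups.

    Cluster 1 is the cluster whose members have the higher mean
    first-component score (deterministic labeling).
    """
    scores = np.asarray(scores, dtype=float)
    n = len(scores)
    if n < 5:
        raise ValueError("need >= 5 patients")
    if n_runs < 1:
        raise ValueError("n_runs must be >= 1")
    rng = np.random.default_rng(seed)
    n_sample = int(np.ceil(resample_rate * n))

    co_cluster = np.zeros((n, n))
    co_sample = np.zeros((n, n))
    for _ in range(n_runs):
        idx = np.sort(rng.choice(n, size=n_sample, replace=False))
        sub = scores[idx]
        labels = fcluster(
            linkage(_pair_dist(sub, distance), method=linkage_method),
            t=k,
            criterion="maxclust",
        )
        same = labels[:, None] == labels[None, :]
        co_sample[np.ix_(idx, idx)] += 1.0
        co_cluster[np.ix_(idx, idx)] += same
    import warnings

    never = (co_sample == 0) & ~np.eye(n, dtype=bool)
    if never.any():
        warnings.warn(
            f"{int(never.sum() / 2)} pair(s) never co-sampled; consensus set to 0",
            stacklevel=2,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        consensus = np.where(co_sample > 0, co_cluster / np.maximum(co_sample, 1), 0.0)
    np.fill_diagonal(consensus, 1.0)
    consensus = (consensus + consensus.T) / 2.0

    final = fcluster(
        linkage(squareform(1.0 - consensus, checks=False), method=linkage_method),
        t=k,
        criterion="maxclust",
    )
    # deterministic labels: cluster 1 has the higher mean PC1 score
    if k == 2 and len(np.unique(final)) == 2:
        means = [scores[final == c, 0].mean() for c in (1, 2)]
        if means[1] > means[0]:
            final = 3 - final
    return ConsensusResult(
        consensus_matrix=consensus,
        assignments=final,
        n_runs=n_runs,
        resample_rate=resample_rate,
    )


class ConsensusCluster(ClusterMixin, BaseEstimator):
    """sklearn-style wrapper: ``fit(X)`` -> ``labels_`` in {1, 2} and
    ``consensus_matrix_``.

    ``use_pca=True`` (default) projects the feature table onto its top
    two principal components before clustering, matching the protocol;
    with ``use_pca=False`` the columns of ``X`` (e.g. the six-feature
    image signature) are clustered directly.
    """

    def __init__(
        self,
        k: int = 2,
        n_runs: int = 50,
        resample_rate: float = 0.8,
        distance: str = "euclidean",
        linkage_method: str = "average",
        use_pca: bool = True,
        random_state: int = 0,
    ):
        self.k = k
        self.n_runs = n_runs
        self.resample_rate = resample_rate
        self.distance = distance
        self.linkage_method = linkage_method
        self.use_pca = use_pca
        self.random_state = random_state

    def fit(self, X, y=None):
        scores = pca_top2(X) if self.use_pca else np.asarray(X, dtype=float)
        result = consensus_cluster(
            scores,
            k=self.k,
            n_runs=self.n_runs,
            resample_rate=self.resample_rate,
            seed=self.random_state,
            distance=self.distance,
            linkage_method=self.linkage_method,
        )
        self.scores_ = scores
        self.consensus_matrix_ = result.consensus_matrix
        self.labels_ = result.assignments
        self.result_ = result
        return self


def cross_tabulate(assignments, labels) -> pd.DataFrame:
    """Cluster x label contingency counts plus per-cluster percentages."""
    assignments = np.asarray(assignments)
    labels = np.asarray(labels)
    if len(assignments) != len(labels):
        raise ValueError("assignments and labels must cover the same patients")
    table = pd.crosstab(
        pd.Series(assignments, name="cluster"), pd.Series(labels, name="label")
    )
    pct = table.div(table.sum(axis=1), axis=0) * 100.0
    pct.columns = [f"pct_{c}" for c in pct.columns]
    return pd.concat([table, pct], axis=1)
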