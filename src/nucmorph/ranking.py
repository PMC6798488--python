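"""Feature-ranking methods used for in-fold top-k selection.

Four rankers, all deterministic (ties broken lexicographically by
feature name):

* ``covariance`` — descending |Pearson correlation| with the 0/1 label
  (point-biserial correlation).
* ``wrst`` — ascending two-sided Wilcoxon rank-sum p-value.  Exact
  enumeration of the rank-sum distribution when both classes have
  <= 10 samples; otherwise the normal approximation with midranks and
  tie correction.
* ``mrmr_mid`` / ``mrmr_miq`` — greedy minimum-redundancy
  maximum-relevance selection on features discretized to 3 states at
  z = +/-1; relevance and redundancy are mutual information in bits; the
  mid variant subtracts mean redundancy, miq divides by it.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm, rankdata
from sklearn.base import BaseEstimator
from sklearn.feature_selection import SelectorMixin

__all__ = [
    "RankingResult",
    "wilcoxon_ranksum",
    "rank_covariance",
    "rank_wrst",
    "rank_mrmr",
    "rank_features",
    "TopFeatureSelector",
    "RANKING_METHODS",
]

RANKING_METHODS = ("covariance", "wrst", "mrmr_mid", "mrmr_miq")


@dataclass
class RankingResult:
    features: list[str]  # best first
    scores: dict[str, float]
    method: str

    def top(self, k: int) -> list[str]:
        return self.features[:k]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "rank": np.arange(1, len(self.features) + 1),
                "feature": self.features,
                "score": [self.scores[f] for f in self.features],
                "method": self.method,
            }
        )


def _as_xy(X, y):
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xv = X.to_numpy(dtype=float)
    else:
        Xv = np.asarray(X, dtype=float)
        names = [f"f{i}" for i in range(Xv.shape[1])]
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError(f"need exactly 2 classes, got {len(classes)}")
    ybin = (y == classes[1]).astype(float)
    return Xv, ybin, names, classes


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

EXACT_MAX_N = 10


@lru_cache(maxsize=64)
def _exact_ranksum_pmf(n: int, m: int) -> np.ndarray:
    """Exact null pmf of the rank sum of a sample of size n out of n+m
    untied observations (ranks 1..n+m); index = rank-sum value."""
    big_n = n + m
    max_w = sum(range(big_n - n + 1, big_n + 1))
    dp = np.zeros((n + 1, max_w + 1))
    dp[0, 0] = 1.0
    for rank_val in range(1, big_n + 1):
        for j in range(min(rank_val, n), 0, -1):
            dp[j, rank_val:] += dp[j - 1, : max_w + 1 - rank_val]
    return dp[n] / dp[n].sum()


@lru_cache(maxsize=16)
def _combo_indices(n: int, m: int) -> np.ndarray:
    return np.array(list(combinations(range(n + m), n)))


def wilcoxon_ranksum(a: np.ndarray, b: np.ndarray, method: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum p-value for a location difference.

    Exact path: when both samples have <= ``EXACT_MAX_N`` observations the
    null distribution of the rank sum W of sample ``a`` over all
    C(n+m, n) assignments of the pooled (mid)ranks is used, giving
    p = P(|W - E[W]| >= |w - E[W]|).  Without ties this distribution is a
    cached exact convolution; with ties it is enumerated directly.
    Larger samples use the normal approximation with midranks and the
    tie-corrected variance.  Returns 1.0 when every pooled value is
    identical.  ``method`` may force ``'exact'`` or ``'approx'``
    (default ``'auto'`` switches on the sample sizes).
    """
    if method not in ("auto", "exact", "approx"):
        raise ValueError("method must be 'auto', 'exact' or 'approx'")
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    ranks = rankdata(pooled)
    n, m = len(a), len(b)
    w = ranks[:n].sum()
    mean_w = n * (ranks.sum() / (n + m))

    use_exact = (
        method == "exact"
        or (method == "auto" and n <= EXACT_MAX_N and m <= EXACT_MAX_N)
    )
    if use_exact:
        target = abs(w - mean_w)
        if len(np.unique(pooled)) == n + m:  # no ties: cached convolution
            pmf = _exact_ranksum_pmf(n, m)
            ws = np.arange(len(pmf), dtype=float)
            return float(pmf[np.abs(ws - mean_w) >= target - 1e-9].sum())
        combos = _combo_indices(n, m)
        ws = ranks[combos].sum(axis=1)
        return float(np.mean(np.abs(ws - mean_w) >= target - 1e-9))

    big_n = n + m
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(counts**3 - counts) / (big_n * (big_n - 1))
    var_w = n * m / 12.0 * (big_n + 1 - tie_term)
    if var_w <= 0:
        return 1.0
    # continuity-corrected z on the rank sum
    z = max(abs(w - mean_w) - 0.5, 0.0) / np.sqrt(var_w)
    return float(min(1.0, 2.0 * norm.sf(z)))


# ---------------------------------------------------------------------------
# Rankers
# ---------------------------------------------------------------------------

def _order(names, scores, descending: bool) -> list[str]:
    """Stable deterministic order: by score, ties by feature name."""
    key = [(-s if descending else s, nm) for s, nm in zip(scores, names)]
    return [nm for _, nm in sorted(zip(key, names))]


def rank_covariance(X, y) -> RankingResult:
    """Descending |point-biserial correlation| with the binary label."""
    Xv, ybin, names, _ = _as_xy(X, y)
    yc = ybin - ybin.mean()
    sy = np.sqrt((yc**2).sum())
    Xc = Xv - Xv.mean(axis=0)
    sx = np.sqrt((Xc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.abs(Xc.T @ yc) / (sx * sy)
    r = np.where(np.isfinite(r), r, -1.0)  # constant features ranked last
    order = _order(names, r, descending=True)
    return RankingResult(order, dict(zip(names, map(float, r))), "covariance")


def rank_wrst(X, y) -> RankingResult:
    """Ascending two-sided rank-sum p-value."""
    Xv, ybin, names, _ = _as_xy(X, y)
    if min((ybin == 0).sum(), (ybin == 1).sum()) < 3:
        raise ValueError("need >= 3 samples per class for WRST ranking")
    ps = np.array(
        [wilcoxon_ranksum(Xv[ybin == 1, j], Xv[ybin == 0, j]) for j in range(Xv.shape[1])]
    )
    order = _order(names, ps, descending=False)
    return RankingResult(order, dict(zip(names, map(float, ps))), "wrst")


def _discretize3(X: np.ndarray) -> np.ndarray:
    """z-score each column and cut at +/-1 into 3 states."""
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd = np.where(sd == 0, 1.0, sd)
    z = (X - mu) / sd
    return (z > -1.0).astype(int) + (z > 1.0).astype(int)


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI in bits between two discrete variables, from joint frequencies."""
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    joint = np.zeros((len(ua), len(ub)))
    np.add.at(joint, (ia, ib), 1.0)
    joint /= joint.sum()
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    nz = joint > 0
    return float(np.sum(joint[nz] * np.log2(joint[nz] / (px @ py)[nz])))


def rank_mrmr(X, y, variant: str = "mid", k: int | None = None) -> RankingResult:
    """Greedy forward mRMR selection of k features.

    First pick maximizes relevance I(f; c); each later pick maximizes
    I(f; c) - mean_s I(f; s) (mid) or I(f; c) / mean_s I(f; s) (miq, with
    the denominator floored at 1e-6).  Ties broken by feature name.
    """
    if variant not in ("mid", "miq"):
        raise ValueError("variant must be 'mid' or 'miq'")
    Xv, ybin, names, _ = _as_xy(X, y)
    n_feat = Xv.shape[1]
    if k is None:
        k = n_feat
    if not 1 <= k <= n_feat:
        raise ValueError(f"k must be in [1, {n_feat}]")
    D = _discretize3(Xv)
    relevance = np.array([mutual_information(D[:, j], ybin) for j in range(n_feat)])

    selected: list[int] = []
    scores: dict[str, float] = {}
    redundancy_cache = np.zeros((n_feat, 0))
    remaining = list(range(n_feat))
    while len(selected) < k:
        if selected:
            last = selected[-1]
            col = np.array(
                [mutual_information(D[:, j], D[:, last]) for j in range(n_feat)]
            )
            redundancy_cache = np.column_stack([redundancy_cache, col])
            red = redundancy_cache[remaining].mean(axis=1)
        else:
            red = np.zeros(len(remaining))
        rel = relevance[remaining]
        if selected:
            obj = rel - red if variant == "mid" else rel / np.maximum(red, 1e-6)
        else:
            obj = rel
        best = min(
            range(len(remaining)), key=lambda i: (-obj[i], names[remaining[i]])
        )
        j = remaining.pop(best)
        selected.append(j)
        scores[names[j]] = float(obj[best])

    order = [names[j] for j in selected]
    for nm in names:
        scores.setdefault(nm, -np.inf)
    return RankingResult(order, scores, f"mrmr_{variant}")


def rank_features(X, y, method: str, k: int | None = None) -> RankingResult:
    """Dispatch to one of the four ranking methods by tag."""
    if method == "covariance":
        return rank_covariance(X, y)
    if method == "wrst":
        return rank_wrst(X, y)
    if method in ("mrmr_mid", "mrmr_miq"):
        return rank_mrmr(X, y, variant=method.split("_")[1], k=k)
    raise ValueError(f"unknown ranking method {method!r}; choose from {RANKING_METHODS}")


class TopFeatureSelector(SelectorMixin, BaseEstimator):
    """Select the top-k features by one of the four ranking methods.

    sklearn-compatible transformer: ``fit`` ranks on the training data
    only, ``transform`` keeps the selected columns.

    Parameters
    ----------
    method : one of {'covariance', 'wrst', 'mrmr_mid', 'mrmr_miq'}
    k : number of features to keep (the protocol default is 3).
    """

    def __init__(self, method: str = "covariance", k: int = 3):
        self.method = method
        self.k = k

    def fit(self, X, y):
        if isinstance(X, pd.DataFrame):
            names = list(X.columns)
            self.feature_names_in_ = np.asarray(names, dtype=object)
        else:
            X = np.asarray(X, dtype=float)
            names = [f"f{i}" for i in range(X.shape[1])]
        if self.k > len(names):
            raise ValueError("k exceeds feature count")
        result = rank_features(X, y, self.method, k=self.k)
        self.ranking_ = result
        self.selected_features_ = result.top(self.k)
        idx = {nm: i for i, nm in enumerate(names)}
        self.support_ = np.zeros(len(names), dtype=bool)
        self.support_[[idx[nm] for nm in self.selected_features_]] = True
        self.n_features_in_ = len(names)
        return self

    def _get_support_mask(self):
        return self.support_
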