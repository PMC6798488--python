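"""Balanced random-subsampling cross-validation protocol.

Each of the 100 iterations: draw an equal number of training patients
from each class (remainder tests), rank features on the training fold
only, keep the top 3, fit the classifier (LDA, ridge-regularized QDA, or
a standardized linear SVM), score the test fold by AUC for the
higher-risk class, and record the mean Bhattacharyya distance of the
selected features between the two classes of the test split.

The canonical task geometries (train counts per class, with the
remainder tested) for a 12 high / 7 intermediate / 43 low cohort are
exposed as ``TASK_TRAIN_SIZES``: high-vs-low 7/7, high-vs-intermediate
4/4, intermediate-vs-low 4/4, high+intermediate-vs-low 10/10,
high-vs-low+intermediate 7/7.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC
from sklearn.utils.validation import check_is_fitted

from .ranking import rank_features
from .separability import mean_bc

__all__ = [
    "RISK_THRESHOLDS",
    "TASK_TRAIN_SIZES",
    "categorize_odx",
    "balanced_split",
    "RidgeQDA",
    "make_classifier",
    "fit_predict",
    "auc",
    "CVConfig",
    "CVResult",
    "run_cv",
    "CLASSIFIERS",
]

CLASSIFIERS = ("lda", "qda", "svm_linear")

# recurrence-score cut points: low < 39, intermediate 39-54, high 55-100
RISK_THRESHOLDS = (39, 55)

TASK_TRAIN_SIZES: dict[str, int] = {
    "high_vs_low": 7,
    "high_vs_intermediate": 4,
    "intermediate_vs_low": 4,
    "high+intermediate_vs_low": 10,
    "high_vs_low+intermediate": 7,
}


def categorize_odx(score: float) -> str:
    """Map a 0-100 recurrence score to its risk category."""
    if not 0 <= score <= 100:
        raise ValueError(f"score must be in [0, 100], got {score}")
    if score < RISK_THRESHOLDS[0]:
        return "low"
    if score < RISK_THRESHOLDS[1]:
        return "intermediate"
    return "high"


def balanced_split(
    y, train_per_class: int, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample ``train_per_class`` indices per class uniformly without
    replacement; everything else is the test set."""
    y = np.asarray(y)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    train: list[np.ndarray] = []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        if len(idx) <= train_per_class:
            raise ValueError(
                f"class {cls!r} has {len(idx)} samples; needs > {train_per_class} "
                "to leave a non-empty test set"
            )
        train.append(rng.choice(idx, size=train_per_class, replace=False))
    train_idx = np.sort(np.concatenate(train))
    test_idx = np.setdiff1d(np.arange(len(y)), train_idx)
    return train_idx, test_idx


class RidgeQDA(ClassifierMixin, BaseEstimator):
    """Quadratic discriminant analysis with a diagonal ridge.

    Per-class Gaussians with full covariance; each class covariance gets
    ``ridge * trace(S)/d`` added to its diagonal so folds with as few as
    4 training samples per class remain non-singular.  ``decision_function``
    returns the log-posterior-odds of the second (positive) class.
    """

    def __init__(self, ridge: float = 1e-3):
        self.ridge = ridge

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if len(self.classes_) != 2:
            raise ValueError("RidgeQDA is a two-class discriminant")
        d = X.shape[1]
        self.means_, self.covs_, self.priors_ = [], [], []
        for cls in self.classes_:
            Xc = X[y == cls]
            mu = Xc.mean(axis=0)
            cov = np.cov(Xc, rowvar=False, ddof=1).reshape(d, d)
            cov = cov + self.ridge * (np.trace(cov) / d) * np.eye(d)
            if np.linalg.matrix_rank(cov) < d:
                raise np.linalg.LinAlgError("singular class covariance after ridge")
            self.means_.append(mu)
            self.covs_.append(cov)
            self.priors_.append(len(Xc) / len(X))
        return self

    def _log_likelihood(self, X):
        X = np.asarray(X, dtype=float)
        out = np.empty((len(X), 2))
        for k in range(2):
            mu, cov = self.means_[k], self.covs_[k]
            diff = X - mu
            sign, logdet = np.linalg.slogdet(cov)
            sol = np.linalg.solve(cov, diff.T).T
            maha = np.sum(diff * sol, axis=1)
            out[:, k] = -0.5 * (maha + logdet) + np.log(self.priors_[k])
        return out

    def decision_function(self, X):
        check_is_fitted(self, "classes_")
        ll = self._log_likelihood(X)
        return ll[:, 1] - ll[:, 0]

    def predict(self, X):
        return self.classes_[(self.decision_function(X) > 0).astype(int)]


def make_classifier(tag: str):
    """Instantiate the classifier for a protocol tag."""
    if tag == "lda":
        return LinearDiscriminantAnalysis()
    if tag == "qda":
        return RidgeQDA()
    if tag == "svm_linear":
        # linear kernel, C = 1, standardized on the training fold
        return make_pipeline(StandardScaler(), SVC(kernel="linear", C=1.0))
    raise ValueError(f"unknown classifier {tag!r}; choose from {CLASSIFIERS}")


def fit_predict(tag: str, X_train, y_train, X_test) -> np.ndarray:
    """Train a classifier and return real-valued scores on the test fold,
    monotone in the predicted probability of the positive (second) class."""
    y_train = np.asarray(y_train)
    if len(np.unique(y_train)) != 2:
        raise ValueError("training fold must contain both classes")
    clf = make_classifier(tag)
    clf.fit(np.asarray(X_train, dtype=float), y_train)
    return np.asarray(clf.decision_function(np.asarray(X_test, dtype=float)))


def auc(scores, labels) -> float:
    """Mann-Whitney AUC with midranks (ties contribute 1/2)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) != 2:
        raise ValueError("need both classes to compute AUC")
    pos = labels == classes[1]
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    ranks = rankdata(scores)
    return float((ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


@dataclass(frozen=True)
class CVConfig:
    """One (ranking method, classifier, task geometry) CV configuration."""

    train_per_class: int
    ranking: str = "covariance"
    classifier: str = "lda"
    n_iter: int = 100
    top_k: int = 3
    positive_class: str | None = None  # default: lexicographically last
    seed: int = 0


@dataclass
class CVResult:
    auc: np.ndarray
    bc: np.ndarray
    top_feature_frequency: dict[str, int]
    config: CVConfig = field(repr=False, default=None)

    @property
    def mean_auc(self) -> float:
        return float(self.auc.mean())

    @property
    def sd_auc(self) -> float:
        return float(self.auc.std(ddof=1))

    @property
    def mean_bc(self) -> float:
        return float(self.bc.mean())


def run_cv(X: pd.DataFrame, y, config: CVConfig) -> CVResult:
    """The full balanced-subsampling CV protocol for one configuration.

    Ranking is computed strictly within the training fold; the positive
    class for AUC is ``config.positive_class`` (the higher-risk class of
    the task) or, by default, the class sorting last.  Deterministic
    given ``config.seed``.
    """
    if not isinstance(X, pd.DataFrame):
        X = pd.DataFrame(np.asarray(X, dtype=float))
        X.columns = [f"f{i}" for i in range(X.shape[1])]
    y = np.asarray(y)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("run_cv handles binary tasks only")
    positive = config.positive_class if config.positive_class is not None else classes[-1]
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} not among {classes}")

    rng = np.random.default_rng(config.seed)
    aucs = np.empty(config.n_iter)
    bcs = np.empty(config.n_iter)
    freq: dict[str, int] = {}
    for it in range(config.n_iter):
        train_idx, test_idx = balanced_split(y, config.train_per_class, rng)
        X_tr, X_te = X.iloc[train_idx], X.iloc[test_idx]
        y_tr, y_te = y[train_idx], y[test_idx]
        ranking = rank_features(X_tr, y_tr, config.ranking, k=config.top_k)
        top = ranking.top(config.top_k)
        for name in top:
            freq[name] = freq.get(name, 0) + 1
        scores = fit_predict(
            config.classifier, X_tr[top], (y_tr == positive).astype(int), X_te[top]
        )
        aucs[it] = auc(scores, (y_te == positive).astype(int))
        bcs[it] = mean_bc(top, X_te, y_te)
    return CVResult(auc=aucs, bc=bcs, top_feature_frequency=freq, config=config)
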