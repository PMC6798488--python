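"""Bhattacharyya-distance separability of class-conditional features.

The Gaussian closed form of the Bhattacharyya distance is used:

    D = (1/4) (mu_a - mu_b)^2 / (s_a^2 + s_b^2)
        + (1/2) ln( (s_a^2 + s_b^2) / (2 s_a s_b) )

with sample variances (ddof=1) floored at 1e-12.  The parametric form is
the deliberate choice here because the protocol evaluates BC on test
splits with as few as 3 samples per class, where histogram estimates of
the Bhattacharyya coefficient are unusable.

A per-CV-iteration "mean BC" averages the distances of the individual
top-ranked features between the two classes of the test split; arrays of
those values across iterations are compared between classification tasks
with the Wilcoxon rank-sum test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ranking import wilcoxon_ranksum

__all__ = ["BCArray", "bc_distance", "mean_bc", "compare_bc_arrays"]

_VAR_FLOOR = 1e-12


@dataclass
class BCArray:
    """Per-iteration mean BC values for one (task, ranking-method) pair."""

    values: np.ndarray
    task: str = ""
    method: str = ""


def bc_distance(sample_a, sample_b) -> float:
    """Gaussian Bhattacharyya distance between two univariate samples."""
    a = np.asarray(sample_a, dtype=float)
    b = np.asarray(sample_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("need >= 2 values per sample")
    va = max(float(np.var(a, ddof=1)), _VAR_FLOOR)
    vb = max(float(np.var(b, ddof=1)), _VAR_FLOOR)
    mu_a, mu_b = float(a.mean()), float(b.mean())
    term1 = 0.25 * (mu_a - mu_b) ** 2 / (va + vb)
    term2 = 0.5 * np.log((va + vb) / (2.0 * np.sqrt(va * vb)))
    return float(term1 + term2)


def mean_bc(top_features: list[str], X_test, y_test) -> float:
    """Mean per-feature BC distance between the two classes on a test split."""
    y = np.asarray(y_test)
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("test split must contain exactly 2 classes")
    values = []
    for name in top_features:
        col = np.asarray(X_test[name], dtype=float)
        values.append(bc_distance(col[y == classes[0]], col[y == classes[1]]))
    return float(np.mean(values))


def compare_bc_arrays(a: BCArray | np.ndarray, b: BCArray | np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value between two BC-distance arrays."""
    av = a.values if isinstance(a, BCArray) else np.asarray(a, dtype=float)
    bv = b.values if isinstance(b, BCArray) else np.asarray(b, dtype=float)
    if av.size == 0 or bv.size == 0:
        raise ValueError("both arrays must be non-empty")
    return wilcoxon_ranksum(av, bv)
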