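"""Shared low-level statistics used across feature families.

Every graph-family feature block reports the same four summary statistics
of a sample of geometric quantities (edge lengths, polygon areas, ...):
mean, standard deviation, min/max ratio, and the bounded
coefficient-of-variation transform

    disorder = 1 - 1 / (1 + sd / mean)

which lives in [0, 1) and is 0 exactly for a perfectly regular sample.
Population standard deviation (ddof=0) is used throughout feature
aggregation so that a single observation has sd 0, not NaN.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "disorder",
    "minmax_ratio",
    "summary4",
    "haralick_stats",
    "HARALICK_STAT_NAMES",
]


def disorder(values: np.ndarray) -> float:
    """Bounded coefficient-of-variation statistic, 1 - 1/(1 + sd/mean).

    Returns 0.0 for empty input or zero mean (a degenerate, perfectly
    regular sample by convention).
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return 0.0
    m = float(np.mean(values))
    s = float(np.std(values))
    if m == 0.0:
        return 0.0
    return 1.0 - 1.0 / (1.0 + s / abs(m))


def minmax_ratio(values: np.ndarray) -> float:
    """min/max ratio on magnitudes; 1.0 when all magnitudes are zero."""
    values = np.abs(np.asarray(values, dtype=float))
    if values.size == 0:
        return 0.0
    mx = float(values.max())
    if mx == 0.0:
        return 1.0
    return float(values.min()) / mx


def summary4(values: np.ndarray) -> dict[str, float]:
    """The {mean, sd, minmax_ratio, disorder} summary of a sample."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        return {"mean": 0.0, "sd": 0.0, "minmax_ratio": 0.0, "disorder": 0.0}
    return {
        "mean": float(np.mean(values)),
        "sd": float(np.std(values)),
        "minmax_ratio": minmax_ratio(values),
        "disorder": disorder(values),
    }


# ---------------------------------------------------------------------------
# Second-order (co-occurrence) statistics
# ---------------------------------------------------------------------------

HARALICK_STAT_NAMES = (
    "contrast_energy",
    "contrast_inverse_moment",
    "contrast_avg",
    "contrast_var",
    "contrast_entropy",
    "intensity_avg",
    "intensity_var",
    "intensity_entropy",
    "entropy",
    "energy",
    "correlation",
    "info_measure1",
    "info_measure2",
)


def _xlog2x(p: np.ndarray) -> np.ndarray:
    """p * log2(p) with the 0*log0 = 0 convention."""
    out = np.zeros_like(p, dtype=float)
    nz = p > 0
    out[nz] = p[nz] * np.log2(p[nz])
    return out


def haralick_stats(p: np.ndarray, *, check: bool = True) -> dict[str, float]:
    """Thirteen second-order statistics of a normalized co-occurrence matrix.

    The matrix ``p`` is B x B, nonnegative and sums to 1 (symmetric in all
    uses here).  Contrast statistics are moments and entropy of the
    inter-bin difference distribution c_k = sum_{|i-j|=k} p(i,j); intensity
    statistics are moments and entropy of the row marginal; the information
    measures of correlation are

        IMC1 = (HXY1 - HXY) / max(HX, HY)
        IMC2 = sqrt(1 - exp(-2 (HXY2 - HXY)))

    where IMC1 is the negation of the classical signed form, so that it is
    nonnegative and grows as the joint distribution departs from the
    product of its marginals (the direction in which orientation disorder
    pushes the co-occurrence structure).  All logarithms are base 2 with
    0*log0 = 0.  Degenerate denominators
    (zero marginal entropy or zero marginal variance) yield 0 for the
    corresponding statistic.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 2 or p.shape[0] != p.shape[1]:
        raise ValueError("co-occurrence matrix must be square")
    total = p.sum()
    if check and not np.isclose(total, 1.0, atol=1e-8):
        raise ValueError(f"co-occurrence matrix must sum to 1 (got {total})")

    b = p.shape[0]
    i = np.arange(b, dtype=float)
    ii, jj = np.meshgrid(i, i, indexing="ij")
    diff = np.abs(ii - jj)

    # difference distribution over k = |i - j|
    c = np.array([p[diff == k].sum() for k in range(b)])
    k = np.arange(b, dtype=float)
    contrast_energy = float((p * (ii - jj) ** 2).sum())
    contrast_inverse_moment = float((p / (1.0 + (ii - jj) ** 2)).sum())
    contrast_avg = float((k * c).sum())
    contrast_var = float(((k - contrast_avg) ** 2 * c).sum())
    contrast_entropy = float(-_xlog2x(c).sum())

    px = p.sum(axis=1)
    py = p.sum(axis=0)
    intensity_avg = float((i * px).sum())
    intensity_var = float(((i - intensity_avg) ** 2 * px).sum())
    intensity_entropy = float(-_xlog2x(px).sum())

    entropy = float(-_xlog2x(p).sum())
    energy = float((p**2).sum())

    mu_x = intensity_avg
    mu_y = float((i * py).sum())
    sig_x = np.sqrt(intensity_var)
    sig_y = np.sqrt(float(((i - mu_y) ** 2 * py).sum()))
    if sig_x > 0 and sig_y > 0:
        correlation = float(((ii * jj * p).sum() - mu_x * mu_y) / (sig_x * sig_y))
    else:
        correlation = 0.0

    hx = intensity_entropy
    hy = float(-_xlog2x(py).sum())
    hxy = entropy
    outer = np.outer(px, py)
    mask = (p > 0) & (outer > 0)
    hxy1 = float(-(p[mask] * np.log2(outer[mask])).sum())
    nz = outer > 0
    hxy2 = float(-(outer[nz] * np.log2(outer[nz])).sum())
    denom = max(hx, hy)
    info1 = float((hxy1 - hxy) / denom) if denom > 0 else 0.0
    arg = 1.0 - np.exp(-2.0 * (hxy2 - hxy))
    info2 = float(np.sqrt(max(arg, 0.0)))

    return {
        "contrast_energy": contrast_energy,
        "contrast_inverse_moment": contrast_inverse_moment,
        "contrast_avg": contrast_avg,
        "contrast_var": contrast_var,
        "contrast_entropy": contrast_entropy,
        "intensity_avg": intensity_avg,
        "intensity_var": intensity_var,
        "intensity_entropy": intensity_entropy,
        "entropy": entropy,
        "energy": energy,
        "correlation": correlation,
        "info_measure1": info1,
        "info_measure2": info2,
    }
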