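"""Per-nucleus shape descriptors and chromatin-texture (GLCM) features.

**Shape** (100): 25 descriptors per nucleus — enclosing-circle ratios,
radial-distance statistics, boundary smoothness, Hu invariant moments,
box-counting fractal dimension of the boundary, Fourier descriptors of
the radial-distance sequence, and ellipse-fit eccentricity — aggregated
across the nuclei of an image by {mean, sd, median, min/max ratio}.

**Haralick texture** (26): per-nucleus gray-level co-occurrence matrices
(64 levels quantized within the nucleus mask, distance 1, four directions
averaged, symmetric, normalized) summarized by the same 13 second-order
statistics used for orientation co-occurrence, aggregated by {mean, sd}.
"""

from __future__ import annotations

import numpy as np
from scipy.interpolate import interp1d
from shapely import minimum_bounding_radius
from shapely.geometry import Polygon
from skimage import measure
from skimage.feature import graycomatrix

from ._stats import HARALICK_STAT_NAMES, haralick_stats, minmax_ratio
from .nuclei import NucleusRecord

__all__ = [
    "shape_descriptors",
    "shape_feature_block",
    "haralick_feature_block",
    "nucleus_glcm",
    "SHAPE_DESCRIPTOR_NAMES",
    "SHAPE_FEATURE_NAMES",
    "HARALICK_FEATURE_NAMES",
]

N_BOUNDARY_SAMPLES = 128
GLCM_LEVELS = 64
MIN_TEXTURE_PIXELS = 16

SHAPE_DESCRIPTOR_NAMES: tuple[str, ...] = (
    ("area_ratio", "dist_ratio", "radial_sd", "radial_var_norm", "perim_ratio",
     "smoothness")
    + tuple(f"hu{i}" for i in range(1, 8))
    + ("fractal_dim",)
    + tuple(f"fd{i}" for i in range(1, 11))
    + ("eccentricity",)
)
assert len(SHAPE_DESCRIPTOR_NAMES) == 25

_SHAPE_AGGS = ("mean", "sd", "median", "minmax_ratio")
SHAPE_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"shape_{d}_{a}" for d in SHAPE_DESCRIPTOR_NAMES for a in _SHAPE_AGGS
)
assert len(SHAPE_FEATURE_NAMES) == 100

HARALICK_FEATURE_NAMES: tuple[str, ...] = tuple(
    f"har_{stat}_{agg}" for stat in HARALICK_STAT_NAMES for agg in ("mean", "sd")
)
assert len(HARALICK_FEATURE_NAMES) == 26


def _resample_closed(points: np.ndarray, n: int) -> np.ndarray:
    """Resample a closed polygon to n points at equal arc length."""
    pts = np.asarray(points, dtype=float)
    if not np.allclose(pts[0], pts[-1]):
        pts = np.vstack([pts, pts[0]])
    seg = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    s = np.concatenate([[0.0], np.cumsum(seg)])
    total = s[-1]
    if total == 0:
        raise ValueError("degenerate boundary (zero perimeter)")
    f = interp1d(s, pts, axis=0)
    return f(np.linspace(0.0, total, n, endpoint=False))


def _box_counting_dimension(points: np.ndarray) -> float:
    """Box-counting fractal dimension of a boundary point set."""
    pts = np.asarray(points, dtype=float)
    pts = pts - pts.min(axis=0)
    span = max(pts.max(), 1e-9)
    sizes = span / np.array([2, 4, 8, 16, 32], dtype=float)
    counts = []
    for s in sizes:
        boxes = {(int(x // s), int(y // s)) for x, y in pts}
        counts.append(len(boxes))
    coeffs = np.polyfit(np.log(1.0 / sizes), np.log(counts), 1)
    return float(coeffs[0])


def _hu_moments(nucleus: NucleusRecord) -> np.ndarray:
    (rows, cols), _ = nucleus.pixels
    r0, c0 = rows.min(), cols.min()
    img = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1))
    img[rows - r0, cols - c0] = 1.0
    mu = measure.moments_central(img)
    nu = measure.moments_normalized(mu)
    return measure.moments_hu(nu)


def shape_descriptors(nucleus: NucleusRecord) -> dict[str, float]:
    """The 25 per-nucleus shape descriptors.

    The boundary is resampled to 128 equal-arc-length points before the
    radial-distance, smoothness and Fourier computations so descriptors
    are comparable across nuclei of different sizes.
    """
    boundary = np.asarray(nucleus.boundary, dtype=float)
    if len(boundary) < 8:
        raise ValueError("boundary must have >= 8 vertices")
    boundary = boundary - boundary.min(axis=0)  # exact translation invariance
    poly = Polygon(boundary)
    if not poly.is_valid or poly.area <= 0:
        poly = poly.buffer(0)
        if poly.is_empty or poly.geom_type != "Polygon":
            raise ValueError("degenerate boundary polygon")

    resampled = _resample_closed(np.asarray(poly.exterior.coords), N_BOUNDARY_SAMPLES)
    centroid = np.array([poly.centroid.x, poly.centroid.y])
    radial = np.linalg.norm(resampled - centroid, axis=1)

    r_enclose = float(minimum_bounding_radius(poly))
    area_ratio = poly.area / (np.pi * r_enclose**2)
    dist_ratio = float(radial.mean() / radial.max())
    radial_sd = float(radial.std())
    radial_var_norm = float(radial.var() / radial.mean() ** 2)
    perim_ratio = float(poly.length / (2.0 * np.pi * r_enclose))
    neighbors_avg = 0.5 * (np.roll(radial, 1) + np.roll(radial, -1))
    smoothness = float(np.mean(np.abs(radial - neighbors_avg)) / radial.mean())

    hu = _hu_moments(nucleus)
    fractal = _box_counting_dimension(np.asarray(poly.exterior.coords)[:-1])

    spectrum = np.abs(np.fft.rfft(radial))
    f0 = max(spectrum[0], 1e-12)
    fds = spectrum[1:11] / f0

    (rows, cols), _ = nucleus.pixels
    r0, c0 = rows.min(), cols.min()
    img = np.zeros((rows.max() - r0 + 1, cols.max() - c0 + 1), dtype=np.uint8)
    img[rows - r0, cols - c0] = 1
    props = measure.regionprops(img)[0]
    ecc = float(props.eccentricity)

    out = {
        "area_ratio": float(area_ratio),
        "dist_ratio": dist_ratio,
        "radial_sd": radial_sd,
        "radial_var_norm": radial_var_norm,
        "perim_ratio": perim_ratio,
        "smoothness": smoothness,
        "fractal_dim": fractal,
        "eccentricity": ecc,
    }
    for i in range(7):
        out[f"hu{i + 1}"] = float(hu[i])
    for i in range(10):
        out[f"fd{i + 1}"] = float(fds[i])
    return {name: out[name] for name in SHAPE_DESCRIPTOR_NAMES}


def shape_feature_block(nuclei: list[NucleusRecord]) -> dict[str, float]:
    """100 shape features: 25 descriptors x {mean, sd, median, min/max ratio}."""
    rows = []
    for nuc in nuclei:
        if len(nuc.boundary) < 8:
            continue
        try:
            rows.append(shape_descriptors(nuc))
        except ValueError:
            continue
    if not rows:
        raise ValueError("no measurable nucleus for shape features")
    table = np.array([[r[d] for d in SHAPE_DESCRIPTOR_NAMES] for r in rows])
    out: dict[str, float] = {}
    for j, d in enumerate(SHAPE_DESCRIPTOR_NAMES):
        col = table[:, j]
        out[f"shape_{d}_mean"] = float(col.mean())
        out[f"shape_{d}_sd"] = float(col.std())
        out[f"shape_{d}_median"] = float(np.median(col))
        out[f"shape_{d}_minmax_ratio"] = minmax_ratio(col)
    return {name: out[name] for name in SHAPE_FEATURE_NAMES}


def nucleus_glcm(nucleus: NucleusRecord, levels: int = GLCM_LEVELS) -> np.ndarray:
    """Symmetric, normalized GLCM of one nucleus.

    Gray levels are quantized to ``levels`` within the nucleus mask;
    pixels outside the nucleus get a sentinel level whose co-occurrence
    rows/columns are discarded, so only within-nucleus adjacencies count.
    Distance-1 offsets in four directions are accumulated and symmetrized.
    """
    (rows, cols), values = nucleus.pixels
    if len(values) < MIN_TEXTURE_PIXELS:
        raise ValueError("nucleus too small for texture")
    r0, c0 = rows.min(), cols.min()
    crop = np.zeros((rows.max() - r0 + 2, cols.max() - c0 + 2), dtype=np.uint16)
    vmin, vmax = values.min(), values.max()
    if vmax > vmin:
        quant = np.floor((values - vmin) / (vmax - vmin + 1e-9) * levels).astype(int)
        quant = np.minimum(quant, levels - 1)
    else:
        quant = np.zeros(len(values), dtype=int)
    crop[rows - r0, cols - c0] = quant + 1  # 0 stays the outside sentinel
    glcm = graycomatrix(
        crop,
        distances=[1],
        angles=[0, np.pi / 4, np.pi / 2, 3 * np.pi / 4],
        levels=levels + 1,
        symmetric=True,
    )
    p = glcm[1:, 1:, 0, :].astype(float).sum(axis=2)  # drop sentinel, pool angles
    total = p.sum()
    if total == 0:
        raise ValueError("no within-nucleus pixel adjacencies")
    return p / total


def haralick_feature_block(
    intensity: np.ndarray, nuclei: list[NucleusRecord], levels: int = GLCM_LEVELS
) -> dict[str, float]:
    """26 texture features: per-nucleus 13 GLCM statistics x {mean, sd}.

    Nuclei with fewer than 16 pixels are skipped; raises if none remain.
    """
    del intensity  # pixel intensities already carried on the records
    rows = []
    for nuc in nuclei:
        try:
            p = nucleus_glcm(nuc, levels=levels)
        except ValueError:
            continue
        stats = haralick_stats(p)
        rows.append([stats[s] for s in HARALICK_STAT_NAMES])
    if not rows:
        raise ValueError("no measurable nucleus for texture features")
    table = np.asarray(rows)
    out: dict[str, float] = {}
    for j, stat in enumerate(HARALICK_STAT_NAMES):
        out[f"har_{stat}_mean"] = float(table[:, j].mean())
        out[f"har_{stat}_sd"] = float(table[:, j].std())
    return {name: out[name] for name in HARALICK_FEATURE_NAMES}
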