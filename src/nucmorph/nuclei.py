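"""Nucleus mask handling and per-nucleus measurement.

Entry point of the pipeline: probability maps are thresholded into binary
masks, connected components become :class:`NucleusRecord` measurements
(centroid, area, boundary, ellipse-fit orientation, intensities), and
images acquired at other magnifications are rescaled to the working
magnification (x20 by convention).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from skimage import measure, transform

__all__ = [
    "ImageMeta",
    "NucleusRecord",
    "threshold_probability_map",
    "label_and_measure",
    "rescale_to_magnification",
    "nucleus_table",
]

MIN_AREA_DEFAULT = 15  # px^2 at x20; removes segmentation specks
THRESHOLD_DEFAULT = 0.5


@dataclass(frozen=True)
class ImageMeta:
    magnification: float
    pixel_size: float = 1.0
    source_id: str = ""

    def __post_init__(self) -> None:
        if self.magnification <= 0:
            raise ValueError("magnification must be > 0")


@dataclass
class NucleusRecord:
    """One segmented nucleus.

    Coordinates are 0-based, x rightward (columns), y downward (rows).
    ``orientation`` is the angle of the ellipse-fit major axis in degrees,
    measured counterclockwise from the +x axis, on [0, 180).
    ``boundary`` is a closed polygon (n, 2) of (x, y) vertices ordered
    counterclockwise.  ``pixels`` holds ((row, col) arrays, gray levels).
    """

    id: int
    centroid: tuple[float, float]
    area: float
    boundary: np.ndarray
    orientation: float
    mean_intensity: float
    pixels: tuple[tuple[np.ndarray, np.ndarray], np.ndarray]


def threshold_probability_map(prob_map: np.ndarray, t: float = THRESHOLD_DEFAULT) -> np.ndarray:
    """Binary mask: pixel true iff probability >= t."""
    prob_map = np.asarray(prob_map, dtype=float)
    if prob_map.min() < 0.0 or prob_map.max() > 1.0:
        raise ValueError("probability map values must lie in [0, 1]")
    return prob_map >= t


def _orientation_deg(region) -> float:
    """Major-axis angle from +x (columns), counterclockwise, in [0, 180).

    skimage's ``orientation`` is measured from the vertical (row) axis in
    (row, col) space; convert to the image-coordinate convention where a
    horizontal elongation is 0 degrees.
    """
    theta = 90.0 - np.rad2deg(region.orientation)
    return float(theta % 180.0)


def _boundary_polygon(region) -> np.ndarray:
    """Closed (x, y) boundary of a region, counterclockwise in image coords."""
    # pad so boundaries touching the bbox edge close properly
    padded = np.pad(region.image, 1)
    contours = measure.find_contours(padded.astype(float), 0.5)
    contour = max(contours, key=len)  # (row, col), on the padded crop
    r0, c0, _, _ = region.bbox
    rows = contour[:, 0] - 1 + r0
    cols = contour[:, 1] - 1 + c0
    poly = np.column_stack([cols, rows])  # (x, y)
    # signed area (shoelace); in y-down image coordinates a clockwise
    # screen loop has positive shoelace area, so flip to make the vertex
    # order counterclockwise in the mathematical sense.
    x, y = poly[:, 0], poly[:, 1]
    signed = 0.5 * np.sum(x * np.roll(y, -1) - np.roll(x, -1) * y)
    if signed > 0:
        poly = poly[::-1]
    return poly


def label_and_measure(
    mask: np.ndarray,
    intensity: np.ndarray,
    min_area: float = MIN_AREA_DEFAULT,
) -> list[NucleusRecord]:
    """Measure connected components (8-connectivity) of area >= min_area.

    ``mask`` may be binary (components are labeled here) or an integer
    label image (labels are respected).
    """
    mask = np.asarray(mask)
    intensity = np.asarray(intensity)
    if mask.shape != intensity.shape:
        raise ValueError("mask and intensity image must have the same shape")
    if mask.dtype == bool or set(np.unique(mask)) <= {0, 1}:
        labels = measure.label(mask > 0, connectivity=2)
    else:
        labels = mask.astype(int)

    records: list[NucleusRecord] = []
    for region in measure.regionprops(labels, intensity_image=intensity):
        if region.area < min_area:
            continue
        ry, rx = region.centroid
        coords = region.coords
        records.append(
            NucleusRecord(
                id=int(region.label),
                centroid=(float(rx), float(ry)),
                area=float(region.area),
                boundary=_boundary_polygon(region),
                orientation=_orientation_deg(region),
                mean_intensity=float(region.intensity_mean),
                pixels=(
                    (coords[:, 0], coords[:, 1]),
                    intensity[coords[:, 0], coords[:, 1]].astype(float),
                ),
            )
        )
    return records


def rescale_to_magnification(
    image: np.ndarray, meta: ImageMeta, target_mag: float, *, is_labels: bool = False
) -> np.ndarray:
    """Rescale an image from ``meta.magnification`` to ``target_mag``.

    Intensity images are area-interpolated (anti-aliased); label masks use
    nearest-neighbor so no interpolated labels appear.
    """
    if target_mag <= 0:
        raise ValueError("target_mag must be > 0")
    factor = target_mag / meta.magnification
    if factor == 1.0:
        return image.copy()
    out_shape = tuple(int(round(s * factor)) for s in image.shape[:2])
    if is_labels:
        out = transform.resize(
            image, out_shape, order=0, preserve_range=True, anti_aliasing=False
        )
        return out.astype(image.dtype)
    out = transform.resize(
        image.astype(float), out_shape, order=1, preserve_range=True,
        anti_aliasing=factor < 1.0,
    )
    return out.astype(image.dtype) if np.issubdtype(image.dtype, np.integer) else out


def nucleus_table(records: list[NucleusRecord]) -> pd.DataFrame:
    """Per-image nucleus table (id, x, y, area, orientation, mean_intensity)."""
    return pd.DataFrame(
        [
            {
                "id": r.id,
                "x": r.centroid[0],
                "y": r.centroid[1],
                "area": r.area,
                "orientation": r.orientation,
                "mean_intensity": r.mean_intensity,
            }
            for r in records
        ]
    )


def write_nucleus_table(records: list[NucleusRecord], path: str | Path) -> None:
    nucleus_table(records).to_csv(path, index=False)
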