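"""Assembly of the full 241-feature histomorphometric vector.

One tissue image (nuclei label mask + grayscale intensity) yields 241
named features partitioned into five families:

==================  =====  ========
family              count  prefix
==================  =====  ========
Global Graph           51  graph_
Shape                 100  shape_
Orientation (CORE)     39  core_
Cell Cluster Graph     25  ccg_
Haralick texture       26  har_
==================  =====  ========
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .ccg import ALPHA_DEFAULT, CCG_FEATURE_NAMES, R_DEFAULT, build_ccg, ccg_feature_block
from .graphs import GRAPH_FEATURE_NAMES, graph_feature_block
from .morphology import (
    HARALICK_FEATURE_NAMES,
    SHAPE_FEATURE_NAMES,
    haralick_feature_block,
    shape_feature_block,
)
from .nuclei import MIN_AREA_DEFAULT, label_and_measure
from .orientation import BIN_COUNT_DEFAULT, CORE_FEATURE_NAMES, core_feature_block

__all__ = ["FEATURE_NAMES", "FEATURE_FAMILIES", "extract_features", "extract_cohort_table"]

FEATURE_FAMILIES: dict[str, tuple[str, ...]] = {
    "graph": GRAPH_FEATURE_NAMES,
    "shape": SHAPE_FEATURE_NAMES,
    "core": CORE_FEATURE_NAMES,
    "ccg": CCG_FEATURE_NAMES,
    "har": HARALICK_FEATURE_NAMES,
}

FEATURE_NAMES: tuple[str, ...] = tuple(
    name for names in FEATURE_FAMILIES.values() for name in names
)
assert len(FEATURE_NAMES) == 241
assert len(set(FEATURE_NAMES)) == 241


def extract_features(
    mask: np.ndarray,
    intensity: np.ndarray,
    *,
    min_area: float = MIN_AREA_DEFAULT,
    ccg_alpha: float = ALPHA_DEFAULT,
    ccg_r: float = R_DEFAULT,
    core_bins: int = BIN_COUNT_DEFAULT,
) -> dict[str, float]:
    """All 241 features of one image; NaN-filled dict if the mask is empty
    or too sparse to support the graph families."""
    nuclei = label_and_measure(mask, intensity, min_area=min_area)
    if len(nuclei) < 8:
        warnings.warn(
            f"only {len(nuclei)} measurable nuclei; feature vector is NaN",
            stacklevel=2,
        )
        return {name: float("nan") for name in FEATURE_NAMES}

    points = np.array([n.centroid for n in nuclei])
    h, w = np.asarray(mask).shape
    bounds = (0.0, 0.0, float(w), float(h))
    ccg = build_ccg(points, alpha=ccg_alpha, r=ccg_r)
    orientations = np.array([n.orientation for n in nuclei])

    out: dict[str, float] = {}
    out.update(graph_feature_block(points, bounds))
    out.update(shape_feature_block(nuclei))
    out.update(core_feature_block(orientations, ccg, b=core_bins))
    out.update(ccg_feature_block(ccg))
    out.update(haralick_feature_block(intensity, nuclei))
    return {name: out[name] for name in FEATURE_NAMES}


def extract_cohort_table(items, **kwargs) -> pd.DataFrame:
    """Feature table for a list of (TissueImage | (mask, intensity), label).

    Returns patients x 241 DataFrame plus a ``label`` column.
    """
    rows = []
    labels = []
    for item, label in items:
        if hasattr(item, "label_mask"):
            mask, intensity = item.label_mask, item.intensity
        else:
            mask, intensity = item
        rows.append(extract_features(mask, intensity, **kwargs))
        labels.append(label)
    table = pd.DataFrame(rows, columns=list(FEATURE_NAMES))
    table["label"] = labels
    return table
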