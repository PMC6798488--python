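"""Cohort manifest handling: exclusions before analysis.

Slides can be unusable for reasons upstream of the pipeline
(non-salvageable tissue, scanning artifacts, missing stain, too little
tumor in the digitized region).  Those exclusions are recorded in an
``exclusion_reason`` column of the cohort manifest and filtered out here
before feature extraction, so the analyzable cohort is an explicit,
auditable subset.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["filter_manifest"]

EXCLUSION_COLUMN = "exclusion_reason"


def filter_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    """Return the analyzable rows of a cohort manifest.

    Rows whose ``exclusion_reason`` is a non-empty string are dropped;
    a missing column means no exclusions.  The result keeps the original
    row order with a fresh index.
    """
    if EXCLUSION_COLUMN not in manifest.columns:
        return manifest.reset_index(drop=True)
    reasons = manifest[EXCLUSION_COLUMN].fillna("").astype(str).str.strip()
    return manifest[reasons == ""].reset_index(drop=True)
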