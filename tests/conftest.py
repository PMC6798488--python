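import numpy as np
import pandas as pd
import pytest

from nucmorph import TissueParams, generate_tissue, label_and_measure
from nucmorph.features import FEATURE_NAMES


@pytest.fixture(scope="session")
def small_tissue():
    """A modest synthetic field reused by several measurement tests."""
    return generate_tissue(TissueParams(n_nuclei=120, field_size=500, seed=42))


@pytest.fixture(scope="session")
def small_nuclei(small_tissue):
    return label_and_measure(small_tissue.label_mask, small_tissue.intensity)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def feature_table():
    """A 55-patient table (12 'high' / 43 'low') of standard-normal
    features on the full 241-name roster; planting is done per-test."""

    def make(seed=0, n_high=12, n_low=43, planted=(), effect=0.0):
        r = np.random.default_rng(seed)
        X = pd.DataFrame(
            r.normal(size=(n_high + n_low, len(FEATURE_NAMES))),
            columns=list(FEATURE_NAMES),
        )
        y = np.array(["high"] * n_high + ["low"] * n_low)
        for name in planted:
            X.loc[y == "high", name] += effect
        return X, y

    return make
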