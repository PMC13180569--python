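import numpy as np
import pandas as pd
import pytest

from bametrics.catalogue import ANALYTES, BileAcidProfile


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def unit_profile():
    return BileAcidProfile({a: 1.0 for a in ANALYTES})


def random_profile(rng) -> BileAcidProfile:
    conc = 10.0 ** rng.normal(-1.0, 0.6, size=len(ANALYTES))
    return BileAcidProfile(dict(zip(ANALYTES, conc)))


@pytest.fixture
def small_cohort_df(rng):
    """Ten subjects, two groups, strictly positive concentrations."""
    rows = []
    for i in range(10):
        conc = 10.0 ** rng.normal(-1.0, 0.5, size=len(ANALYTES))
        row = dict(zip(ANALYTES, conc))
        row["subject_id"] = f"S{i:03d}"
        row["group"] = "NMOSD_AQP4neg" if i < 5 else "MS"
        rows.append(row)
    return pd.DataFrame(rows)


@pytest.fixture
def binormal_marker(rng):
    """Scores/labels for a well-separated two-class marker (AUC ~ 0.96)."""
    pos = rng.normal(2.56 / np.sqrt(2) * np.sqrt(2), 1.0, size=32)
    neg = rng.normal(0.0, 1.0, size=50)
    scores = np.concatenate([pos, neg])
    labels = np.array([1] * 32 + [0] * 50)
    return scores, labels
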