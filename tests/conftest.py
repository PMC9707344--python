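"""Shared fixtures: small synthetic recordings and cohorts.

Everything is generated at test time from seeded generators; module-scoped
fixtures cache the expensive cohorts so the suite stays fast.
"""

import warnings

import numpy as np
import pytest

from dne import SyntheticSpec, Test, gen_cohort, gen_ft, gen_saw, preset
from dne.pipeline import cohort_features, extract_features

warnings.filterwarnings("ignore", category=FutureWarning)


@pytest.fixture(scope="session")
def ft_normal_features():
    rec, spec = gen_ft(preset(Test.FT, seed=1))
    return extract_features(rec), spec


@pytest.fixture(scope="session")
def ft_abnormal_features():
    rec, spec = gen_ft(preset(Test.FT, impaired=True, seed=1))
    return extract_features(rec), spec


@pytest.fixture(scope="session")
def saw_normal():
    rec, spec = gen_saw(SyntheticSpec(test=Test.SAW, seed=1))
    return rec, spec


@pytest.fixture(scope="session")
def ft_cohort_table():
    items = gen_cohort(20, Test.FT, seed=11)
    return cohort_features(items)


def gaussian_feature_frame(n_subjects=20, n_features=8, effect=3.0, seed=0):
    """Simple two-class tabular stand-in for classifier unit tests (no pose)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    for s in range(n_subjects):
        for label in ("normal", "abnormal"):
            for device in ("tablet", "phone"):
                x = rng.normal(0, 1, n_features)
                if label == "abnormal":
                    x[0] += effect
                    x[1] -= effect / 2
                row = {"subject_id": f"S{s:02d}", "test": "FT", "label": label, "device": device}
                row.update({f"f{i}": x[i] for i in range(n_features)})
                rows.append(row)
    return pd.DataFrame(rows)
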