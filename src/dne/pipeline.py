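"""End-to-end glue: preprocess a recording and extract its test's features."""

from __future__ import annotations

from typing import Iterable, Sequence

import pandas as pd

from .featureset import FeatureSet
from .gait import GaitConfig, extract_saw
from .preprocessing import PreprocessConfig, preprocess
from .skeleton import Recording, Test
from .synthetic import CohortItem
from .upper_limb import UpperLimbConfig, extract_fr, extract_ft, extract_ftf


def extract_features(
    rec: Recording,
    preprocess_cfg: PreprocessConfig | None = None,
    upper_cfg: UpperLimbConfig | None = None,
    gait_cfg: GaitConfig | None = None,
    already_preprocessed: bool = False,
) -> FeatureSet:
    """Normalize + smooth a raw recording and run the test's extractor."""
    rec.validate()
    if not already_preprocessed:
        rec = preprocess(rec, preprocess_cfg)
    if rec.test is Test.FT:
        return extract_ft(rec, upper_cfg)
    if rec.test is Test.FTF:
        return extract_ftf(rec, upper_cfg)
    if rec.test is Test.FR:
        return extract_fr(rec, upper_cfg)
    if rec.test is Test.SAW:
        return extract_saw(rec, gait_cfg)
    raise ValueError(f"unknown test {rec.test}")


def features_to_frame(features: Sequence[FeatureSet]) -> pd.DataFrame:
    """Feature sets -> one analysis DataFrame (same layout as the CSV format)."""
    names: list[str] = []
    for f in features:
        for n in f.names():
            if n not in names:
                names.append(n)
    rows = []
    for f in features:
        row = {"subject_id": f.subject_id, "test": f.test.value, "label": f.label, "device": f.device}
        row.update({n: f.values.get(n, float("nan")) for n in names})
        rows.append(row)
    return pd.DataFrame(rows, columns=["subject_id", "test", "label", "device"] + names)


def cohort_features(items: Iterable[CohortItem], **kwargs) -> pd.DataFrame:
    """Extract features for every cohort recording into one DataFrame."""
    return features_to_frame([extract_features(it.recording, **kwargs) for it in items])
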