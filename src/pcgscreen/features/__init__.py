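"""Feature extraction: the 31-feature representation of one 30-s record."""

from __future__ import annotations

from typing import Iterable

import pandas as pd

from ..preprocess import PCGRecord
from .acoustic import (
    AcousticConfig,
    AcousticFeatures,
    CalibratedSignal,
    SpecificLoudnessPattern,
    acoustic_features,
    calibrate,
    fluctuation_feature,
    loudness_feature,
    roughness_feature,
    sharpness_feature,
    specific_loudness,
)
from .basic import (
    ACOUSTIC_NAMES,
    FEATURE_NAMES,
    FREQUENCY_NAMES,
    PERCEPTUAL_NAMES,
    TIME_NAMES,
    FeatureVector,
    FrequencyFeatures,
    PSDEstimate,
    TimeFeatures,
    assemble_feature_vector,
    compute_frequency_features,
    compute_time_features,
    estimate_psd,
)
from .perceptual import MFCCConfig, PerceptualFeatures, mfcc_features

__all__ = [
    "ACOUSTIC_NAMES",
    "FEATURE_NAMES",
    "FREQUENCY_NAMES",
    "PERCEPTUAL_NAMES",
    "TIME_NAMES",
    "AcousticConfig",
    "AcousticFeatures",
    "CalibratedSignal",
    "FeatureVector",
    "FrequencyFeatures",
    "MFCCConfig",
    "PSDEstimate",
    "PerceptualFeatures",
    "SpecificLoudnessPattern",
    "TimeFeatures",
    "acoustic_features",
    "assemble_feature_vector",
    "calibrate",
    "compute_frequency_features",
    "compute_time_features",
    "estimate_psd",
    "extract_features",
    "feature_table",
    "fluctuation_feature",
    "loudness_feature",
    "mfcc_features",
    "roughness_feature",
    "sharpness_feature",
    "specific_loudness",
]


def extract_features(
    rec: PCGRecord,
    mfcc_config: MFCCConfig | None = None,
    acoustic_config: AcousticConfig | None = None,
) -> FeatureVector:
    """Compute the full 31-element feature vector of a preprocessed record."""
    ac = acoustic_features(rec, acoustic_config or AcousticConfig())
    fr = compute_frequency_features(estimate_psd(rec))
    ti = compute_time_features(rec)
    pe = mfcc_features(rec, mfcc_config)
    return assemble_feature_vector(ac, fr, ti, pe)


def feature_table(
    records: Iterable[PCGRecord],
    include_acoustic: bool = True,
    mfcc_config: MFCCConfig | None = None,
    acoustic_config: AcousticConfig | None = None,
) -> pd.DataFrame:
    """Build the per-subject feature table.

    Columns are ``subject_id``, ``label``, then the feature names in
    canonical order -- all 31, or 27 when ``include_acoustic`` is False
    (the ablation that drops the psychoacoustic group). The column order is
    part of the CSV format contract.
    """
    rows = []
    for rec in records:
        row: dict[str, object] = {"subject_id": rec.subject_id, "label": rec.label}
        if include_acoustic:
            row.update(extract_features(rec, mfcc_config, acoustic_config).as_dict())
        else:
            fr = compute_frequency_features(estimate_psd(rec))
            ti = compute_time_features(rec)
            pe = mfcc_features(rec, mfcc_config)
            row.update(dict(zip(FREQUENCY_NAMES, fr.as_array())))
            row.update(dict(zip(TIME_NAMES, ti.as_array())))
            row.update(pe.as_dict())
        rows.append(row)
    names = FEATURE_NAMES if include_acoustic else FEATURE_NAMES[4:]
    return pd.DataFrame(rows, columns=["subject_id", "label", *names])
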