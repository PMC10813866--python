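"""Canonical CT radiomics feature schema and table ingestion.

The pipeline consumes a per-patient radiomics table produced upstream by
a standard IBSI-compliant extractor run on 1 x 1 x 1 mm B-spline
resampled pre-treatment CT (documented provenance, not re-implemented
here).  This module pins the canonical 851-name schema — shape,
first-order and five texture families on the original image, plus
first-order and texture families on the 8 wavelet sub-bands — and
validates user tables against it.  Schema conformance is advisory:
synthetic cohorts use generic feature names (f1..fK) and proceed with a
warning.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

__all__ = [
    "enumerate_radiomics_schema",
    "read_radiomics_table",
    "validate_schema",
    "SchemaReport",
    "RADIOMICS_FEATURE_CLASSES",
    "WAVELET_SUBBANDS",
]

_SHAPE = (
    "Elongation", "Flatness", "LeastAxisLength", "MajorAxisLength",
    "Maximum2DDiameterColumn", "Maximum2DDiameterRow", "Maximum2DDiameterSlice",
    "Maximum3DDiameter", "MeshVolume", "MinorAxisLength", "Sphericity",
    "SurfaceArea", "SurfaceVolumeRatio", "VoxelVolume",
)

_FIRSTORDER = (
    "10Percentile", "90Percentile", "Energy", "Entropy", "InterquartileRange",
    "Kurtosis", "Maximum", "MeanAbsoluteDeviation", "Mean", "Median", "Minimum",
    "Range", "RobustMeanAbsoluteDeviation", "RootMeanSquared", "Skewness",
    "TotalEnergy", "Uniformity", "Variance",
)

_GLCM = (
    "Autocorrelation", "ClusterProminence", "ClusterShade", "ClusterTendency",
    "Contrast", "Correlation", "DifferenceAverage", "DifferenceEntropy",
    "DifferenceVariance", "Id", "Idm", "Idmn", "Idn", "Imc1", "Imc2",
    "InverseVariance", "JointAverage", "JointEnergy", "JointEntropy", "MCC",
    "MaximumProbability", "SumAverage", "SumEntropy", "SumSquares",
)

_GLRLM = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelRunEmphasis", "LongRunEmphasis",
    "LongRunHighGrayLevelEmphasis", "LongRunLowGrayLevelEmphasis",
    "LowGrayLevelRunEmphasis", "RunEntropy", "RunLengthNonUniformity",
    "RunLengthNonUniformityNormalized", "RunPercentage", "RunVariance",
    "ShortRunEmphasis", "ShortRunHighGrayLevelEmphasis",
    "ShortRunLowGrayLevelEmphasis",
)

_GLSZM = (
    "GrayLevelNonUniformity", "GrayLevelNonUniformityNormalized",
    "GrayLevelVariance", "HighGrayLevelZoneEmphasis", "LargeAreaEmphasis",
    "LargeAreaHighGrayLevelEmphasis", "LargeAreaLowGrayLevelEmphasis",
    "LowGrayLevelZoneEmphasis", "SizeZoneNonUniformity",
    "SizeZoneNonUniformityNormalized", "SmallAreaEmphasis",
    "SmallAreaHighGrayLevelEmphasis", "SmallAreaLowGrayLevelEmphasis",
    "ZoneEntropy", "ZonePercentage", "ZoneVariance",
)

_GLDM = (
    "DependenceEntropy", "DependenceNonUniformity",
    "DependenceNonUniformityNormalized", "DependenceVariance",
    "GrayLevelNonUniformity", "GrayLevelVariance", "HighGrayLevelEmphasis",
    "LargeDependenceEmphasis", "LargeDependenceHighGrayLevelEmphasis",
    "LargeDependenceLowGrayLevelEmphasis", "LowGrayLevelEmphasis",
    "SmallDependenceEmphasis", "SmallDependenceHighGrayLevelEmphasis",
    "SmallDependenceLowGrayLevelEmphasis",
)

_NGTDM = ("Busyness", "Coarseness", "Complexity", "Contrast", "Strength")

RADIOMICS_FEATURE_CLASSES: dict[str, tuple[str, ...]] = {
    "shape": _SHAPE,           # 14, original image only
    "firstorder": _FIRSTORDER, # 18
    "glcm": _GLCM,             # 24
    "glrlm": _GLRLM,           # 16
    "glszm": _GLSZM,           # 16
    "gldm": _GLDM,             # 14
    "ngtdm": _NGTDM,           # 5
}

# high/low-pass combinations applied along the three axes of a 3D image
WAVELET_SUBBANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

_TEXTURE_AND_INTENSITY = ("firstorder", "glcm", "glrlm", "glszm", "gldm", "ngtdm")


def enumerate_radiomics_schema() -> list[str]:
    """Ordered canonical feature names: 107 original + 8 x 93 wavelet = 851.

    Shape features describe the segmented mask geometry and are therefore
    computed on the original image only; intensity and texture families
    repeat on every wavelet sub-band.  Names follow the
    ``{imagetype}_{class}_{feature}`` convention with the dotted wavelet
    prefix (``wavelet.HLL_glszm_GrayLevelVariance``).
    """
    names = [f"original_shape_{f}" for f in _SHAPE]
    for cls in _TEXTURE_AND_INTENSITY:
        names.extend(f"original_{cls}_{f}" for f in RADIOMICS_FEATURE_CLASSES[cls])
    for band in WAVELET_SUBBANDS:
        for cls in _TEXTURE_AND_INTENSITY:
            names.extend(f"wavelet.{band}_{cls}_{f}" for f in RADIOMICS_FEATURE_CLASSES[cls])
    return names


@dataclass
class SchemaReport:
    missing: list[str] = field(default_factory=list)
    extra: list[str] = field(default_factory=list)
    coverage: float = 0.0


def validate_schema(table: pd.DataFrame, schema: list[str] | None = None) -> SchemaReport:
    """Compare a table's columns against the canonical schema (never mutates)."""
    if schema is None:
        schema = enumerate_radiomics_schema()
    cols = set(table.columns)
    sset = set(schema)
    missing = sorted(sset - cols)
    extra = sorted(cols - sset)
    coverage = (len(sset) - len(missing)) / len(sset) if sset else 0.0
    if extra:
        warnings.warn(
            f"{len(extra)} non-schema column(s) in radiomics table "
            f"(first few: {extra[:3]}); proceeding — schema conformance is advisory")
    return SchemaReport(missing=missing, extra=extra, coverage=coverage)


def read_radiomics_table(path: str | Path) -> tuple[pd.DataFrame, SchemaReport]:
    """Read a patients x features radiomics CSV keyed by ``patient_id``.

    All feature cells must be numeric; offending cells are reported in the
    error.  Returns the table (patient_id index) and an advisory schema
    report.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as e:
        raise ValueError(f"radiomics table {path} is empty") from e
    if "patient_id" not in df.columns:
        raise ValueError(f"radiomics table {path} has no 'patient_id' column")
    if df["patient_id"].duplicated().any():
        dupes = df.loc[df["patient_id"].duplicated(), "patient_id"].tolist()
        raise ValueError(f"duplicate patient_id values: {dupes}")
    df = df.set_index("patient_id")
    coerced = df.apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna() & df.notna()
    if bad.to_numpy().any():
        cells = [
            (str(idx), str(col))
            for col in bad.columns
            for idx in bad.index[bad[col]]
        ]
        raise ValueError(f"non-numeric cells in radiomics table: {cells[:10]}"
                         + (" ..." if len(cells) > 10 else ""))
    return coerced, validate_schema(coerced)
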