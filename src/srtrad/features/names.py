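"""Canonical naming of the 3072 radiomic features.

A feature is identified by (region, filter, family, statistic, sequence) and
rendered as a single string, e.g.::

    Tumour_Histogram_Minimum_T2
    Edema_LBP_Median_T1
    Tumour-Margin_Geometric_Convexity_T1
    Lesion-Margin_Wavelet_I_LHL__GLCM_MaximumProbability_T2

The string form round-trips through :func:`parse_feature_name`.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass

REGIONS = ("Tumour", "Edema", "Tumour-Margin", "Lesion-Margin")
SEQUENCES = ("T1", "T2")
WAVELET_BANDS = ("LLL", "LLH", "LHL", "LHH", "HLL", "HLH", "HHL", "HHH")

GEOMETRIC_STATS = (
    "Volume",
    "SurfaceArea",
    "Maximum3DDiameter",
    "Sphericity",
    "Compactness",
    "Convexity",
    "Elongation",
    "Flatness",
)

HISTOGRAM_STATS = (
    "Mean",
    "Median",
    "Minimum",
    "Maximum",
    "Range",
    "Variance",
    "StandardDeviation",
    "Skewness",
    "Kurtosis",
    "Energy",
    "Entropy",
    "MeanAbsoluteDeviation",
    "RobustMeanAbsoluteDeviation",
    "Percentile10",
    "Percentile90",
    "InterquartileRange",
)

GLCM_STATS = (
    "MaximumProbability",
    "JointEnergy",
    "JointEntropy",
    "Contrast",
    "Dissimilarity",
    "InverseDifferenceMoment",
    "InverseDifference",
    "Correlation",
    "Autocorrelation",
    "ClusterShade",
    "ClusterProminence",
    "ClusterTendency",
    "JointAverage",
    "JointVariance",
    "SumAverage",
    "SumVariance",
    "SumEntropy",
    "DifferenceAverage",
    "DifferenceVariance",
    "DifferenceEntropy",
    "IMC1",
    "IMC2",
    "IDMN",
    "IDN",
)

FAMILIES = ("Geometric", "Histogram", "LBP", "GLCM")

#: features per (region × sequence) block:
#: 8 geometric + 16 histogram + 16 LBP + 24 GLCM + 8 bands × (16 + 24) = 384
BLOCK_SIZE = (
    len(GEOMETRIC_STATS)
    + len(HISTOGRAM_STATS)
    + len(HISTOGRAM_STATS)  # LBP block reuses the histogram statistics
    + len(GLCM_STATS)
    + len(WAVELET_BANDS) * (len(HISTOGRAM_STATS) + len(GLCM_STATS))
)
N_FEATURES = len(REGIONS) * len(SEQUENCES) * BLOCK_SIZE  # 3072


@dataclass(frozen=True)
class FeatureName:
    """Structured identity of one radiomic feature."""

    region: str       # Tumour | Edema | Tumour-Margin | Lesion-Margin
    filter: str       # "Original" or one of the wavelet band labels LLL..HHH
    family: str       # Geometric | Histogram | LBP | GLCM
    statistic: str
    sequence: str     # T1 | T2

    def __post_init__(self) -> None:
        if self.region not in REGIONS:
            raise ValueError(f"unknown region {self.region!r}")
        if self.sequence not in SEQUENCES:
            raise ValueError(f"unknown sequence {self.sequence!r}")
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family {self.family!r}")
        if self.filter != "Original" and self.filter not in WAVELET_BANDS:
            raise ValueError(f"unknown filter {self.filter!r}")

    def __str__(self) -> str:
        if self.filter == "Original":
            return f"{self.region}_{self.family}_{self.statistic}_{self.sequence}"
        return (
            f"{self.region}_Wavelet_I_{self.filter}__"
            f"{self.family}_{self.statistic}_{self.sequence}"
        )


_WAVELET_RE = re.compile(
    r"^(?P<region>Tumour-Margin|Lesion-Margin|Tumour|Edema)"
    r"_Wavelet_I_(?P<band>[LH]{3})__"
    r"(?P<family>Histogram|GLCM)_(?P<stat>\w+?)_(?P<seq>T1|T2)$"
)
_PLAIN_RE = re.compile(
    r"^(?P<region>Tumour-Margin|Lesion-Margin|Tumour|Edema)"
    r"_(?P<family>Geometric|Histogram|LBP|GLCM)_(?P<stat>\w+?)_(?P<seq>T1|T2)$"
)


def parse_feature_name(name: str) -> FeatureName:
    """Parse the string form back into a :class:`FeatureName`."""
    m = _WAVELET_RE.match(name)
    if m:
        return FeatureName(
            m["region"], m["band"], m["family"], m["stat"], m["seq"]
        )
    m = _PLAIN_RE.match(name)
    if m:
        return FeatureName(m["region"], "Original", m["family"], m["stat"], m["seq"])
    raise ValueError(f"unparseable feature name {name!r}")


def block_feature_names(region: str, sequence: str) -> list[FeatureName]:
    """The 384 features of one (region, sequence) block, in canonical order."""
    out: list[FeatureName] = []
    out += [FeatureName(region, "Original", "Geometric", s, sequence) for s in GEOMETRIC_STATS]
    out += [FeatureName(region, "Original", "Histogram", s, sequence) for s in HISTOGRAM_STATS]
    out += [FeatureName(region, "Original", "LBP", s, sequence) for s in HISTOGRAM_STATS]
    out += [FeatureName(region, "Original", "GLCM", s, sequence) for s in GLCM_STATS]
    for band in WAVELET_BANDS:
        out += [FeatureName(region, band, "Histogram", s, sequence) for s in HISTOGRAM_STATS]
        out += [FeatureName(region, band, "GLCM", s, sequence) for s in GLCM_STATS]
    assert len(out) == BLOCK_SIZE
    return out


def all_feature_names() -> list[str]:
    """The canonical 3072-long column order of the feature table."""
    names = [
        str(f)
        for region, sequence in itertools.product(REGIONS, SEQUENCES)
        for f in block_feature_names(region, sequence)
    ]
    assert len(names) == N_FEATURES
    return names
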