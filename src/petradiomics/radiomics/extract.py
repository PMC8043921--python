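"""Assembly of the full 101-feature vector.

Family cardinalities are fixed by the extraction protocol: 19 morphological,
2 local-intensity, 18 intensity-statistical, 25 co-occurrence (GLCM), 16
run-length (GLRLM), 16 size-zone (GLSZM) and 5 neighbourhood gray-tone
difference (NGTDM) features — 101 in total.  Beyond the conventional metrics
(volume, TLG, SUVmax/peak/mean) and the named model features (Moran's I,
Geary's C, inverse variance, second measure of information correlation,
coarseness, elongation, long-run low gray-level emphasis), family membership
follows the canonical standardized (IBSI-style) family lists trimmed to the
stated counts; the exact membership of the remaining features is a
documented assumption of this implementation, not a reported fact.

Features that are undefined for a given input are reported as NaN together
with a reason flag, never silently dropped or zeroed, so downstream
screening can exclude them explicitly.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd

from ..petio import PETVolume, ROIMask
from .discretize import DiscretizedROI, discretize
from .intensity import LOCAL_FEATURES, STAT_FEATURES, intensity_statistics, suv_peak
from .morphology import MORPHOLOGY_FEATURES, morphology_features
from .texture import (
    GLCM_FEATURES,
    GLRLM_FEATURES,
    GLSZM_FEATURES,
    NGTDM_FEATURES,
    glcm_features,
    glrlm_features,
    glszm_features,
    ngtdm_features,
)

__all__ = ["ExtractionConfig", "FeatureVector", "FEATURE_NAMES", "FAMILY_COUNTS", "extract_all"]

FAMILY_COUNTS = {
    "morph": 19,
    "loc": 2,
    "stat": 18,
    "glcm": 25,
    "glrlm": 16,
    "glszm": 16,
    "ngtdm": 5,
}

FEATURE_NAMES: tuple[str, ...] = tuple(
    [f"morph.{n}" for n in MORPHOLOGY_FEATURES]
    + [f"loc.{n}" for n in LOCAL_FEATURES]
    + [f"stat.{n}" for n in STAT_FEATURES]
    + [f"glcm.{n}" for n in GLCM_FEATURES]
    + [f"glrlm.{n}" for n in GLRLM_FEATURES]
    + [f"glszm.{n}" for n in GLSZM_FEATURES]
    + [f"ngtdm.{n}" for n in NGTDM_FEATURES]
)
assert len(FEATURE_NAMES) == 101


@dataclass
class ExtractionConfig:
    """Extraction settings.

    ``discretization`` is ``"fbs"`` (fixed bin size, ``bin_param`` = width in
    SUV, default 0.5) or ``"fbn"`` (fixed bin number, ``bin_param`` = Nb).
    ``texture_aggregation`` controls GLCM/GLRLM direction handling:
    ``"average"`` (feature values averaged over the 13 directions, default)
    or ``"merge"`` (single direction-summed matrix).  ``max_exact_autocorr``
    bounds the exact O(N^2) Moran/Geary computation.
    """

    discretization: str = "fbs"
    bin_param: float = 0.5
    texture_aggregation: str = "average"
    max_exact_autocorr: int = 20000

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


@dataclass
class FeatureVector:
    """101 named feature values plus undefined-value flags and provenance."""

    values: dict[str, float]
    flags: dict[str, str] = field(default_factory=dict)
    config_hash: str = ""

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != FEATURE_NAMES:
            missing = set(FEATURE_NAMES) - set(self.values)
            extra = set(self.values) - set(FEATURE_NAMES)
            raise ValueError(f"feature vector malformed; missing={missing}, extra={extra}")

    def __len__(self) -> int:
        return len(self.values)

    def family_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for name in self.values:
            fam = name.split(".", 1)[0]
            counts[fam] = counts.get(fam, 0) + 1
        return counts

    def to_series(self, name=None) -> pd.Series:
        return pd.Series(self.values, name=name)


def extract_all(vol: PETVolume, mask: ROIMask, config: ExtractionConfig | None = None) -> FeatureVector:
    """Extract all 101 features from a PET volume and its tumor mask.

    Deterministic given (volume, mask, config).  Per-feature undefined
    values surface as NaN entries with a reason in ``flags``.
    """
    if config is None:
        config = ExtractionConfig()
    mask.check_grid(vol)

    values: dict[str, float] = {}
    flags: dict[str, str] = {}

    def take(prefix: str, vals: dict, fl: dict, expected: tuple[str, ...]) -> None:
        for k in expected:
            values[f"{prefix}.{k}"] = float(vals[k]) if vals[k] is not None else np.nan
        for k, reason in fl.items():
            flags[f"{prefix}.{k}"] = reason

    v, f = morphology_features(mask, vol)
    take("morph", v, f, MORPHOLOGY_FEATURES)
    v, f = suv_peak(vol, mask)
    take("loc", v, f, LOCAL_FEATURES)
    v, f = intensity_statistics(vol, mask, max_exact_autocorr=config.max_exact_autocorr)
    take("stat", v, f, STAT_FEATURES)

    d: DiscretizedROI = discretize(vol, mask, method=config.discretization, param=config.bin_param)
    for note in d.flags:
        flags["_discretization"] = note
    v, f = glcm_features(d, aggregation=config.texture_aggregation)
    take("glcm", v, f, GLCM_FEATURES)
    v, f = glrlm_features(d, aggregation=config.texture_aggregation)
    take("glrlm", v, f, GLRLM_FEATURES)
    v, f = glszm_features(d)
    take("glszm", v, f, GLSZM_FEATURES)
    v, f = ngtdm_features(d)
    take("ngtdm", v, f, NGTDM_FEATURES)

    ordered = {name: values[name] for name in FEATURE_NAMES}
    return FeatureVector(ordered, flags, config.hash())
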