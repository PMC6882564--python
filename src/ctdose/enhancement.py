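"""Per-patient contrast enhancement and arm-level descriptive statistics.

Contrast enhancement is the change in CT number: the post-contrast HU
minus the unenhanced HU at the same site.  For the aorta this uses the
hepatic arterial phase (HAP) measurement; for the hepatic parenchyma the
right and left lobes are averaged (equal weights) in both phases before
subtraction, which for equal weights is the same as averaging the
per-lobe differences.

Arm comparisons follow standard practice for a two-arm observational
study: a two-sample t test on continuous measures (pooled-variance
Student form by default, Welch available) and a Pearson chi-square test
on the male/female ratio.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PatientRecord
from .errors import MeasurementError

__all__ = [
    "EnhancementSample",
    "AttainmentResult",
    "ComparisonResult",
    "AORTA_THRESHOLD_HU",
    "LIVER_THRESHOLD_HU",
    "compute_enhancement",
    "compute_enhancements",
    "attainment_rate",
    "two_sample_t",
    "chi_square_2x2",
    "enhancement_to_frame",
    "write_enhancement_csv",
]

#: Diagnostic enhancement thresholds (HU): strict ">" attainment.
AORTA_THRESHOLD_HU = 280.0
LIVER_THRESHOLD_HU = 50.0

_HU_FIELDS = (
    "aorta_unenh_hu",
    "aorta_hap_hu",
    "liver_r_unenh_hu",
    "liver_l_unenh_hu",
    "liver_r_pvp_hu",
    "liver_l_pvp_hu",
)


@dataclass(frozen=True)
class EnhancementSample:
    """Derived contrast enhancement (ΔHU) for one patient.

    ``flags`` names the sites ("aorta", "liver") whose enhancement is
    non-positive; such values are kept in descriptive statistics but are
    flagged so the dose transformation can exclude them explicitly.
    """

    patient_id: str
    protocol_kvp: int
    aorta_enh: float
    liver_enh: float
    flags: tuple[str, ...] = ()

    def value(self, site: str) -> float:
        if site == "aorta":
            return self.aorta_enh
        if site == "liver":
            return self.liver_enh
        raise ValueError(f"unknown site {site!r}; expected 'aorta' or 'liver'")


class AttainmentResult(NamedTuple):
    """Count and proportion of values strictly above a threshold."""

    k: int
    n: int
    rate: float


@dataclass(frozen=True)
class ComparisonResult:
    statistic: float
    degrees_of_freedom: float
    p_value: float
    test_name: str

    def __post_init__(self):
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError(f"p_value outside [0, 1]: {self.p_value}")


def compute_enhancement(record: PatientRecord) -> EnhancementSample:
    """ΔHU per site: aorta HAP − unenhanced; liver mean(R, L) PVP −
    mean(R, L) unenhanced."""
    for field in _HU_FIELDS:
        v = getattr(record, field)
        if v is None or not math.isfinite(v):
            raise MeasurementError(
                f"patient {record.patient_id}: field '{field}' is missing or non-finite"
            )
    aorta_enh = record.aorta_hap_hu - record.aorta_unenh_hu
    liver_enh = (
        (record.liver_r_pvp_hu + record.liver_l_pvp_hu) / 2.0
        - (record.liver_r_unenh_hu + record.liver_l_unenh_hu) / 2.0
    )
    flags = tuple(
        site for site, v in (("aorta", aorta_enh), ("liver", liver_enh)) if v <= 0
    )
    return EnhancementSample(
        patient_id=record.patient_id,
        protocol_kvp=record.protocol_kvp,
        aorta_enh=aorta_enh,
        liver_enh=liver_enh,
        flags=flags,
    )


def compute_enhancements(records: Iterable[PatientRecord]) -> list[EnhancementSample]:
    return [compute_enhancement(r) for r in records]


def attainment_rate(values: Sequence[float], threshold: float) -> AttainmentResult:
    """Empirical attainment: the count and proportion of enhancement
    values strictly greater than ``threshold``."""
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise ValueError("attainment_rate requires a non-empty collection")
    k = int(np.count_nonzero(x > threshold))
    return AttainmentResult(k=k, n=int(x.size), rate=k / x.size)


def two_sample_t(
    group_a: Sequence[float], group_b: Sequence[float], pooled: bool = True
) -> ComparisonResult:
    """Two-sample t test, two-sided.

    ``pooled=True`` gives the classical Student test with a pooled
    variance estimate and n1+n2−2 degrees of freedom; ``pooled=False``
    gives the Welch form.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        raise ValueError("both groups have zero variance; t test undefined")
    res = stats.ttest_ind(a, b, equal_var=pooled)
    return ComparisonResult(
        statistic=float(res.statistic),
        degrees_of_freedom=float(res.df),
        p_value=float(res.pvalue),
        test_name="student-t" if pooled else "welch-t",
    )


def chi_square_2x2(
    counts_a: tuple[int, int],
    counts_b: tuple[int, int],
    continuity_correction: bool = False,
) -> ComparisonResult:
    """Pearson chi-square test on a 2x2 table of (male, female) counts
    for two groups; df = 1, no Yates correction by default."""
    table = np.asarray([counts_a, counts_b], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be non-negative")
    if (table.sum(axis=0) <= 0).any() or (table.sum(axis=1) <= 0).any():
        raise ValueError("every row and column margin must be positive")
    res = stats.chi2_contingency(table, correction=continuity_correction)
    return ComparisonResult(
        statistic=float(res.statistic),
        degrees_of_freedom=float(res.dof),
        p_value=float(res.pvalue),
        test_name="pearson-chi2" + ("-yates" if continuity_correction else ""),
    )


def enhancement_to_frame(samples: Iterable[EnhancementSample]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": s.patient_id,
            "protocol_kvp": s.protocol_kvp,
            "aorta_enh_hu": s.aorta_enh,
            "liver_enh_hu": s.liver_enh,
        }
        for s in samples
    ]
    return pd.DataFrame(rows, columns=["patient_id", "protocol_kvp", "aorta_enh_hu", "liver_enh_hu"])


def write_enhancement_csv(samples: Iterable[EnhancementSample], path: str | Path) -> None:
    enhancement_to_frame(samples).to_csv(path, index=False)
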