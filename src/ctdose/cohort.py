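"""Synthetic patient cohorts for hepatic dynamic CT protocol studies.

Each cohort emulates one protocol arm of a two-arm hepatic dynamic CT
study: ``n`` patients scanned at a fixed tube voltage (100 or 120 kVp)
after a weight-adjusted contrast injection (default 2.0 mL/kg of a
300 mgI/mL agent, i.e. 600 mgI/kg).  Per patient the generator emits the
raw CT numbers (Hounsfield units) that the downstream analysis consumes:
the abdominal aorta on the unenhanced scan and in the hepatic arterial
phase (HAP), and the right/left hepatic lobes on the unenhanced scan and
in the portal venous phase (PVP).

Contrast enhancement (post-contrast minus unenhanced HU) is drawn from a
normal distribution truncated below at 10% of its mean — enhancement is
positive by construction, and the truncation keeps the reciprocal
dose transformation downstream well behaved.  With ``moment_match=True``
the drawn enhancements are affinely rescaled so that the sample mean and
sample SD (n−1 convention) equal the specified arm moments exactly,
which lets an analysis reproduce published summary statistics without
the raw data.

Unenhanced baselines and demographics are plumbing: the analysis uses
only HU differences, so baselines cancel, and age/sex/height/weight do
not feed the inference.  They are generated anyway so that cohort files
carry a realistic schema.
"""

from __future__ import annotations

import dataclasses
import io
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import CohortParseError, InvalidSpecError

__all__ = [
    "ArmSpec",
    "PatientRecord",
    "COHORT_COLUMNS",
    "VALID_KVP",
    "default_arm_spec",
    "generate_cohort",
    "moment_match",
    "cohort_to_frame",
    "frame_to_cohort",
    "write_cohort_csv",
    "read_cohort_csv",
]

VALID_KVP = (100, 120)

#: Column order of the cohort CSV interchange format.
COHORT_COLUMNS = [
    "patient_id",
    "protocol_kvp",
    "sex",
    "age",
    "height_cm",
    "weight_kg",
    "administered_ml_per_kg",
    "aorta_unenh_hu",
    "aorta_hap_hu",
    "liver_r_unenh_hu",
    "liver_l_unenh_hu",
    "liver_r_pvp_hu",
    "liver_l_pvp_hu",
]

#: Enhancement values are truncated below at this fraction of the mean.
TRUNCATION_FRACTION = 0.10

#: SD (HU) of the symmetric right/left lobe offset around the patient's
#: parenchymal enhancement; the offsets cancel under lobe averaging.
LOBE_OFFSET_SD = 3.0

# Published arm-level enhancement moments (HU): mean, SD for the aorta in
# the hepatic arterial phase and the hepatic parenchyma in the portal
# venous phase, per tube voltage.
ARM_MOMENTS = {
    120: {"aorta": (340.9, 51.4), "liver": (57.8, 11.8)},
    100: {"aorta": (395.9, 65.1), "liver": (73.9, 15.5)},
}


@dataclass(frozen=True)
class ArmSpec:
    """Parameters of one synthetic protocol arm.

    Enhancement moments are in HU; ``administered_volume`` is the
    injected contrast volume per kg body weight (mL/kg).  Baseline
    (unenhanced) moments are plumbing constants — only HU differences
    reach the analysis.
    """

    protocol_kvp: int
    n: int
    aorta_enh_mean: float
    aorta_enh_sd: float
    liver_enh_mean: float
    liver_enh_sd: float
    aorta_baseline_mean: float = 45.0
    aorta_baseline_sd: float = 5.0
    liver_baseline_mean: float = 58.0
    liver_baseline_sd: float = 6.0
    administered_volume: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.protocol_kvp not in VALID_KVP:
            raise InvalidSpecError(
                f"protocol_kvp must be one of {VALID_KVP}, got {self.protocol_kvp}"
            )
        if self.n < 2:
            raise InvalidSpecError(f"n must be >= 2, got {self.n}")
        for name in ("aorta_enh_sd", "liver_enh_sd", "aorta_baseline_sd", "liver_baseline_sd"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be > 0, got {getattr(self, name)}")
        for name in ("aorta_enh_mean", "liver_enh_mean"):
            if getattr(self, name) <= 0:
                raise InvalidSpecError(f"{name} must be > 0, got {getattr(self, name)}")
        if self.administered_volume <= 0:
            raise InvalidSpecError(
                f"administered_volume must be > 0, got {self.administered_volume}"
            )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ArmSpec":
        return cls(**d)


def default_arm_spec(protocol_kvp: int, n: int = 100, seed: int = 0, **overrides) -> ArmSpec:
    """Arm spec preloaded with the published enhancement moments for the
    given tube voltage (100 or 120 kVp)."""
    if protocol_kvp not in ARM_MOMENTS:
        raise InvalidSpecError(f"no default moments for {protocol_kvp} kVp")
    aorta = ARM_MOMENTS[protocol_kvp]["aorta"]
    liver = ARM_MOMENTS[protocol_kvp]["liver"]
    kwargs = dict(
        protocol_kvp=protocol_kvp,
        n=n,
        aorta_enh_mean=aorta[0],
        aorta_enh_sd=aorta[1],
        liver_enh_mean=liver[0],
        liver_enh_sd=liver[1],
        seed=seed,
    )
    kwargs.update(overrides)
    return ArmSpec(**kwargs)


@dataclass(frozen=True)
class PatientRecord:
    """One patient's protocol arm, anthropometrics, administered dose and
    raw CT numbers (HU)."""

    patient_id: str
    protocol_kvp: int
    sex: str
    age: float
    height_cm: float
    weight_kg: float
    administered_ml_per_kg: float
    aorta_unenh_hu: float
    aorta_hap_hu: float
    liver_r_unenh_hu: float
    liver_l_unenh_hu: float
    liver_r_pvp_hu: float
    liver_l_pvp_hu: float


def moment_match(values: Sequence[float], mean: float, sd: float) -> np.ndarray:
    """Affinely rescale ``values`` so the sample mean and sample SD
    (n−1 convention) equal ``mean`` and ``sd`` exactly."""
    x = np.asarray(values, dtype=float)
    if x.size < 2:
        raise InvalidSpecError("moment matching needs at least 2 values")
    s = x.std(ddof=1)
    if s == 0:
        raise InvalidSpecError("cannot moment-match a zero-variance sample")
    if sd <= 0:
        raise InvalidSpecError(f"target sd must be > 0, got {sd}")
    return (x - x.mean()) * (sd / s) + mean


def _truncated_normal(rng, mean, sd, floor, size):
    a = (floor - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort(spec: ArmSpec, moment_match_flag: bool = True) -> list[PatientRecord]:
    """Generate ``spec.n`` synthetic patients for one protocol arm.

    Enhancement is drawn from a normal truncated below at 10% of the arm
    mean; with ``moment_match_flag`` the aortic and hepatic enhancement
    samples are rescaled to hit the arm moments exactly.  The right/left
    hepatic lobes are the patient's parenchymal enhancement plus/minus a
    symmetric offset, so their average equals the drawn enhancement.
    Identical spec (including seed) yields an identical cohort.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n

    aorta_enh = _truncated_normal(
        rng, spec.aorta_enh_mean, spec.aorta_enh_sd,
        TRUNCATION_FRACTION * spec.aorta_enh_mean, n,
    )
    liver_enh = _truncated_normal(
        rng, spec.liver_enh_mean, spec.liver_enh_sd,
        TRUNCATION_FRACTION * spec.liver_enh_mean, n,
    )
    if moment_match_flag:
        aorta_enh = moment_match(aorta_enh, spec.aorta_enh_mean, spec.aorta_enh_sd)
        liver_enh = moment_match(liver_enh, spec.liver_enh_mean, spec.liver_enh_sd)

    aorta_base = rng.normal(spec.aorta_baseline_mean, spec.aorta_baseline_sd, size=n)
    liver_base = rng.normal(spec.liver_baseline_mean, spec.liver_baseline_sd, size=n)
    # symmetric offsets: right = value + d, left = value - d, so the
    # equal-weight lobe mean reproduces the drawn quantity exactly
    base_offset = rng.normal(0.0, LOBE_OFFSET_SD, size=n)
    enh_offset = rng.normal(0.0, LOBE_OFFSET_SD, size=n)

    # demographics: thin adults with chronic liver disease; schema
    # realism only, never used by the inference
    sex = np.where(rng.random(n) < 0.6, "M", "F")
    age = np.clip(rng.normal(69.0, 10.0, size=n), 30.0, 90.0)
    height = np.where(
        sex == "M", rng.normal(163.0, 6.0, size=n), rng.normal(151.0, 6.0, size=n)
    )
    weight = np.clip(rng.normal(55.0, 10.0, size=n), 35.0, None)

    records = []
    for i in range(n):
        liver_r_unenh = liver_base[i] + base_offset[i]
        liver_l_unenh = liver_base[i] - base_offset[i]
        records.append(
            PatientRecord(
                patient_id=f"{spec.protocol_kvp}kVp-{i + 1:04d}",
                protocol_kvp=spec.protocol_kvp,
                sex=str(sex[i]),
                age=round(float(age[i]), 1),
                height_cm=round(float(height[i]), 1),
                weight_kg=round(float(weight[i]), 1),
                administered_ml_per_kg=spec.administered_volume,
                aorta_unenh_hu=float(aorta_base[i]),
                aorta_hap_hu=float(aorta_base[i] + aorta_enh[i]),
                liver_r_unenh_hu=float(liver_r_unenh),
                liver_l_unenh_hu=float(liver_l_unenh),
                liver_r_pvp_hu=float(liver_r_unenh + liver_enh[i] + enh_offset[i]),
                liver_l_pvp_hu=float(liver_l_unenh + liver_enh[i] - enh_offset[i]),
            )
        )
    return records


def cohort_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    records = list(records)
    if not records:
        raise InvalidSpecError("cannot serialise an empty cohort")
    return pd.DataFrame([dataclasses.asdict(r) for r in records], columns=COHORT_COLUMNS)


_NUMERIC_COLUMNS = [
    c for c in COHORT_COLUMNS if c not in ("patient_id", "sex", "protocol_kvp")
]


def frame_to_cohort(frame: pd.DataFrame) -> list[PatientRecord]:
    """Validate a cohort table and convert it to records.

    Raises :class:`CohortParseError` naming the offending row and column
    on missing columns, non-numeric values or unknown protocol values.
    """
    missing = [c for c in COHORT_COLUMNS if c not in frame.columns]
    if missing:
        raise CohortParseError(f"cohort table is missing column(s): {', '.join(missing)}")
    if len(frame) == 0:
        raise CohortParseError("cohort table contains no rows")

    frame = frame.copy()
    for col in _NUMERIC_COLUMNS + ["protocol_kvp"]:
        converted = pd.to_numeric(frame[col], errors="coerce")
        bad = converted.isna() & frame[col].notna() | frame[col].isna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise CohortParseError(
                f"non-numeric or missing value in column '{col}', row {row}"
            )
        frame[col] = converted

    kvp = frame["protocol_kvp"].astype(int)
    bad_kvp = ~kvp.isin(VALID_KVP)
    if bad_kvp.any():
        row = int(np.flatnonzero(bad_kvp.to_numpy())[0])
        raise CohortParseError(
            f"unknown protocol_kvp {frame['protocol_kvp'].iloc[row]!r} in row {row}; "
            f"expected one of {VALID_KVP}"
        )

    records = []
    for i, row in frame.iterrows():
        records.append(
            PatientRecord(
                patient_id=str(row["patient_id"]),
                protocol_kvp=int(row["protocol_kvp"]),
                sex=str(row["sex"]),
                age=float(row["age"]),
                height_cm=float(row["height_cm"]),
                weight_kg=float(row["weight_kg"]),
                administered_ml_per_kg=float(row["administered_ml_per_kg"]),
                aorta_unenh_hu=float(row["aorta_unenh_hu"]),
                aorta_hap_hu=float(row["aorta_hap_hu"]),
                liver_r_unenh_hu=float(row["liver_r_unenh_hu"]),
                liver_l_unenh_hu=float(row["liver_l_unenh_hu"]),
                liver_r_pvp_hu=float(row["liver_r_pvp_hu"]),
                liver_l_pvp_hu=float(row["liver_l_pvp_hu"]),
            )
        )
    return records


def write_cohort_csv(records: Iterable[PatientRecord], path: str | Path) -> None:
    """Write records to the cohort CSV interchange format (UTF-8,
    '.' decimal separator, one row per patient)."""
    frame = cohort_to_frame(records)
    # repr gives the shortest round-trip float representation
    frame.to_csv(path, index=False, float_format=lambda v: repr(float(v)))


def read_cohort_csv(path: str | Path) -> list[PatientRecord]:
    """Read and validate a cohort CSV; see :func:`frame_to_cohort`."""
    path = Path(path)
    try:
        frame = pd.read_csv(
            path, dtype={"patient_id": str, "sex": str}, float_precision="round_trip"
        )
    except (pd.errors.EmptyDataError, io.UnsupportedOperation) as exc:
        raise CohortParseError(f"{path}: empty or unreadable cohort CSV") from exc
    try:
        return frame_to_cohort(frame)
    except CohortParseError as exc:
        raise CohortParseError(f"{path}: {exc}") from None
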