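"""Required contrast-medium volume per patient.

The quantity modelled by the Bayesian stage is not enhancement itself
but the contrast volume per kilogram that would have brought a patient's
enhancement exactly to the diagnostic threshold.  At a fixed injection
duration and iodine concentration, enhancement is proportional to the
iodine dose per kg, so

    required_volume = administered_volume * threshold / enhancement

with the algebraic identity required_volume * enhancement =
administered_volume * threshold.  A patient who enhanced twice the
threshold would have needed half the administered volume; a patient
exactly at threshold needed exactly what was given.

The reciprocal blows up as enhancement approaches zero, so samples at or
below a positivity floor (threshold/10 by default) are excluded — each
exclusion is signalled with the patient id, never silently dropped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .enhancement import AORTA_THRESHOLD_HU, LIVER_THRESHOLD_HU, EnhancementSample
from .errors import AllPatientsExcludedError, EnhancementBelowFloorError

__all__ = [
    "RequiredVolumeSample",
    "TransformResult",
    "SITE_THRESHOLDS",
    "required_volume",
    "transform_cohort",
    "required_volume_to_frame",
    "write_required_volume_csv",
]

logger = logging.getLogger(__name__)

#: Diagnostic thresholds per target site (HU).
SITE_THRESHOLDS = {"aorta": AORTA_THRESHOLD_HU, "liver": LIVER_THRESHOLD_HU}

#: Fraction of the threshold below which enhancement is considered
#: unusable for the reciprocal transformation.
FLOOR_FRACTION = 0.10


@dataclass(frozen=True)
class RequiredVolumeSample:
    """Contrast volume (mL/kg) one patient would have needed to reach
    the diagnostic threshold."""

    patient_id: str
    protocol_kvp: int
    site: str
    threshold: float
    administered_volume: float
    required_volume: float


@dataclass(frozen=True)
class TransformResult:
    """Retained required-volume samples plus the ids excluded at the
    positivity floor."""

    samples: tuple[RequiredVolumeSample, ...]
    excluded_ids: tuple[str, ...]

    @property
    def values(self) -> np.ndarray:
        return np.array([s.required_volume for s in self.samples])

    @property
    def n_excluded(self) -> int:
        return len(self.excluded_ids)


def required_volume(
    enhancement: float,
    threshold: float,
    administered_volume: float,
    floor: float | None = None,
    patient_id: str | None = None,
) -> float:
    """Volume (mL/kg) needed to bring ``enhancement`` to ``threshold``
    under dose-enhancement proportionality.

    Raises :class:`EnhancementBelowFloorError` (carrying ``patient_id``)
    when enhancement is at or below the positivity floor.
    """
    if threshold <= 0:
        raise ValueError(f"threshold must be > 0, got {threshold}")
    if administered_volume <= 0:
        raise ValueError(f"administered_volume must be > 0, got {administered_volume}")
    if floor is None:
        floor = FLOOR_FRACTION * threshold
    if enhancement <= floor:
        raise EnhancementBelowFloorError(
            f"enhancement {enhancement:.3g} HU at or below floor {floor:.3g} HU"
            + (f" (patient {patient_id})" if patient_id else ""),
            patient_id=patient_id,
        )
    return administered_volume * threshold / enhancement


def transform_cohort(
    samples: Iterable[EnhancementSample],
    site: str,
    administered_volume: float = 2.0,
    threshold: float | None = None,
) -> TransformResult:
    """Transform a cohort's enhancements at one site into required
    volumes; excluded patients are reported, and logged at INFO."""
    samples = list(samples)
    if not samples:
        raise ValueError("transform_cohort requires a non-empty collection")
    if site not in SITE_THRESHOLDS:
        raise ValueError(f"unknown site {site!r}; expected one of {sorted(SITE_THRESHOLDS)}")
    if threshold is None:
        threshold = SITE_THRESHOLDS[site]

    retained: list[RequiredVolumeSample] = []
    excluded: list[str] = []
    for s in samples:
        try:
            v = required_volume(
                s.value(site), threshold, administered_volume, patient_id=s.patient_id
            )
        except EnhancementBelowFloorError:
            excluded.append(s.patient_id)
            continue
        retained.append(
            RequiredVolumeSample(
                patient_id=s.patient_id,
                protocol_kvp=s.protocol_kvp,
                site=site,
                threshold=threshold,
                administered_volume=administered_volume,
                required_volume=v,
            )
        )
    if excluded:
        logger.info(
            "%s: excluded %d/%d patients below the enhancement floor: %s",
            site, len(excluded), len(samples), ", ".join(excluded),
        )
    if not retained:
        raise AllPatientsExcludedError(
            f"all {len(samples)} patients fell below the enhancement floor for site {site!r}"
        )
    return TransformResult(samples=tuple(retained), excluded_ids=tuple(excluded))


def required_volume_to_frame(samples: Sequence[RequiredVolumeSample]) -> pd.DataFrame:
    rows = [
        {
            "patient_id": s.patient_id,
            "protocol_kvp": s.protocol_kvp,
            "site": s.site,
            "required_ml_per_kg": s.required_volume,
        }
        for s in samples
    ]
    return pd.DataFrame(
        rows, columns=["patient_id", "protocol_kvp", "site", "required_ml_per_kg"]
    )


def write_required_volume_csv(
    samples: Sequence[RequiredVolumeSample], path: str | Path
) -> None:
    required_volume_to_frame(samples).to_csv(path, index=False)
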