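"""Exception hierarchy for ctdose.

All package errors derive from :class:`CtDoseError` so callers can catch
one base class; most also derive from ``ValueError`` because they signal
invalid inputs rather than internal failures.
"""

from __future__ import annotations


class CtDoseError(Exception):
    """Base class for all ctdose errors."""


class InvalidSpecError(CtDoseError, ValueError):
    """A cohort or study specification violates its invariants."""


class CohortParseError(CtDoseError, ValueError):
    """A cohort CSV could not be parsed; message names the row/column."""


class MeasurementError(CtDoseError, ValueError):
    """A patient record is missing or has a non-finite CT number."""


class EnhancementBelowFloorError(CtDoseError, ValueError):
    """Enhancement at or below the positivity floor: the reciprocal dose
    transformation is unreliable and the sample must be excluded.

    Carries ``patient_id`` so the caller can log which patient was dropped.
    """

    def __init__(self, message: str, patient_id: str | None = None):
        super().__init__(message)
        self.patient_id = patient_id


class AllPatientsExcludedError(CtDoseError, ValueError):
    """Every patient fell below the enhancement floor; nothing to model."""


class McmcError(CtDoseError, ValueError):
    """Invalid MCMC configuration or data incompatible with the prior."""


class UndefinedMomentsError(CtDoseError, ValueError):
    """Closed-form posterior moments do not exist at this sample size."""


class IncompleteReportError(CtDoseError, ValueError):
    """A study report is missing cells required for rendering."""
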