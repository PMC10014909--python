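"""Exception hierarchy for the NILS package."""


class NilsError(Exception):
    """Base class for all package errors."""


class InvalidRecordError(NilsError):
    """A patient record violates a field-level invariant."""


class EncodingError(NilsError):
    """A record cannot be encoded for the requested model variant."""


class IneligibleRecordError(NilsError):
    """A record is missing a mandatory variable and cannot be predicted."""


class TrainingError(NilsError):
    """MLP or ensemble training failed (degenerate data or non-finite loss)."""


class UndefinedMetricError(NilsError):
    """A requested classification metric has a zero denominator."""


class CohortCSVError(NilsError):
    """A cohort CSV file failed validation; message carries the row number."""
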