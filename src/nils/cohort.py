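"""Patient records and the deterministic encoding of the 10 input variables.

The staging tool consumes 10 preoperative variables per patient: largest
tumor size, vascular invasion (VI), multifocality, ER status, histological
type, PR status, mode of detection, age at diagnosis, tumor localization
(laterality + clock position, or "central"), and Ki67.  Four model variants
exist, differing in which variables they consume:

============  ======  =============================================
variant       inputs  contents
============  ======  =============================================
``n0_full``   16      all 10 variables (VI included)
``n0_reduced``  13    VI included; ER, PR, Ki67 dropped
``vi_full``   15      all variables except VI (VI is the target)
``vi_reduced``  12    VI, ER, PR, Ki67 all absent
============  ======  =============================================

Continuous variables (tumor size, age, Ki67) are standardized to zero mean
and unit standard deviation using statistics fitted on the training cohort;
histological type and localization are one-hot encoded; the remaining
variables are 0/1 indicators.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, field, replace  # noqa: F401  (replace re-exported)
from typing import Iterable, Optional, Sequence, Union

import numpy as np

from .exceptions import CohortCSVError, EncodingError, InvalidRecordError

__all__ = [
    "Variant",
    "Quadrant",
    "PatientRecord",
    "NormalizationStats",
    "EncodedInput",
    "map_localization",
    "fit_normalization",
    "encode_record",
    "read_cohort_csv",
    "write_cohort_csv",
    "VARIABLE_NAMES",
]

#: the 10 input variables, in importance-rank order (used for permutation ranking)
VARIABLE_NAMES = (
    "tumor_size",
    "vi",
    "multifocality",
    "er",
    "histological_type",
    "pr",
    "detection_mode",
    "age",
    "localization",
    "ki67",
)


class Variant(str, enum.Enum):
    """The four model variants of the prediction workflow."""

    N0_FULL = "n0_full"
    N0_REDUCED = "n0_reduced"
    VI_FULL = "vi_full"
    VI_REDUCED = "vi_reduced"

    @property
    def input_dim(self) -> int:
        return {"n0_full": 16, "n0_reduced": 13, "vi_full": 15, "vi_reduced": 12}[
            self.value
        ]

    @property
    def uses_vi(self) -> bool:
        """VI is an input to the N0 models only."""
        return self in (Variant.N0_FULL, Variant.N0_REDUCED)

    @property
    def uses_receptors(self) -> bool:
        """Whether ER, PR and Ki67 are inputs (the *_full variants)."""
        return self in (Variant.N0_FULL, Variant.VI_FULL)


class Quadrant(str, enum.Enum):
    CENTRAL = "central"
    UIQ = "UIQ"
    UOQ = "UOQ"
    LIQ = "LIQ"
    LOQ = "LOQ"


LOCALIZATION_ORDER = (
    Quadrant.CENTRAL,
    Quadrant.UIQ,
    Quadrant.UOQ,
    Quadrant.LIQ,
    Quadrant.LOQ,
)

HISTOLOGICAL_TYPES = ("NST", "ILC", "other")


@dataclass(frozen=True)
class PatientRecord:
    """One patient's input variables plus an optional nodal-status label.

    Missing values are represented by ``None`` and are permitted only for
    ``vi``, ``er``, ``pr`` and ``ki67_percent`` in prediction-eligible
    records.  ``multifocality`` may be ``None`` to model ineligible records
    (they are rejected at routing, not at construction).
    """

    patient_id: str
    age_years: float
    detection_mode: str  # "screening" | "symptomatic"
    tumor_size_mm: float
    multifocality: Optional[bool]
    histological_type: str  # "NST" | "ILC" | "other"
    laterality: Optional[str]  # "right" | "left"; None only when position=="central"
    position: Union[float, str]  # clock hour in (0, 12] or "central"
    vi: Optional[bool] = None
    er: Optional[bool] = None  # True = positive
    pr: Optional[bool] = None
    ki67_percent: Optional[float] = None
    nodal_status: Optional[str] = None  # "N0" | "N+"

    def __post_init__(self) -> None:
        if not (self.age_years > 0):
            raise InvalidRecordError(f"{self.patient_id}: age_years must be > 0")
        if not (self.tumor_size_mm > 0):
            raise InvalidRecordError(f"{self.patient_id}: tumor_size_mm must be > 0")
        if self.detection_mode not in ("screening", "symptomatic"):
            raise InvalidRecordError(
                f"{self.patient_id}: detection_mode {self.detection_mode!r}"
            )
        if self.histological_type not in HISTOLOGICAL_TYPES:
            raise InvalidRecordError(
                f"{self.patient_id}: histological_type {self.histological_type!r}"
            )
        if self.position != "central":
            h = self.position
            if not isinstance(h, (int, float)) or not (0 < float(h) <= 12):
                raise InvalidRecordError(
                    f"{self.patient_id}: clock position must be in (0, 12] or 'central'"
                )
            if self.laterality not in ("right", "left"):
                raise InvalidRecordError(
                    f"{self.patient_id}: laterality required for a non-central tumor"
                )
        if self.ki67_percent is not None and not (0 <= self.ki67_percent <= 100):
            raise InvalidRecordError(
                f"{self.patient_id}: ki67_percent outside [0, 100]"
            )
        if self.nodal_status not in (None, "N0", "N+"):
            raise InvalidRecordError(
                f"{self.patient_id}: nodal_status {self.nodal_status!r}"
            )

    @property
    def localization(self) -> Quadrant:
        return map_localization(self.laterality, self.position)

    @property
    def is_n0(self) -> Optional[bool]:
        if self.nodal_status is None:
            return None
        return self.nodal_status == "N0"


def map_localization(laterality: Optional[str], position: Union[float, str]) -> Quadrant:
    """Map laterality + clock position to a breast quadrant (or central).

    The clock face is read with the examiner facing the patient; ``h' = h mod
    12`` and sectors are half-open so boundary hours (3, 6, 9, 12) fall in
    the sector they open.  Right breast: [0,3) UIQ, [3,6) LIQ, [6,9) LOQ,
    [9,12) UOQ; the left breast mirrors inner<->outer.
    """
    if position == "central":
        return Quadrant.CENTRAL
    h = float(position)
    if not (0 < h <= 12):
        raise InvalidRecordError(f"clock position {h} outside (0, 12]")
    if laterality not in ("right", "left"):
        raise InvalidRecordError("laterality required for a non-central position")
    hp = h % 12.0
    sector = int(hp // 3)  # 0..3
    right = (Quadrant.UIQ, Quadrant.LIQ, Quadrant.LOQ, Quadrant.UOQ)
    left = (Quadrant.UOQ, Quadrant.LOQ, Quadrant.LIQ, Quadrant.UIQ)
    return right[sector] if laterality == "right" else left[sector]


@dataclass(frozen=True)
class NormalizationStats:
    """Per-variable mean/SD used to standardize the continuous inputs.

    SDs use the sample (n-1) denominator and are computed over non-missing
    training values only.
    """

    tumor_size_mean: float
    tumor_size_sd: float
    age_mean: float
    age_sd: float
    ki67_mean: float
    ki67_sd: float
    n_tumor_size: int
    n_age: int
    n_ki67: int

    def __post_init__(self) -> None:
        for name in ("tumor_size_sd", "age_sd", "ki67_sd"):
            if not getattr(self, name) > 0:
                raise InvalidRecordError(f"{name} must be > 0")

    def to_dict(self) -> dict:
        return {
            "tumor_size_mm": {
                "mean": self.tumor_size_mean,
                "sd": self.tumor_size_sd,
                "n": self.n_tumor_size,
            },
            "age_years": {"mean": self.age_mean, "sd": self.age_sd, "n": self.n_age},
            "ki67_percent": {
                "mean": self.ki67_mean,
                "sd": self.ki67_sd,
                "n": self.n_ki67,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationStats":
        return cls(
            tumor_size_mean=d["tumor_size_mm"]["mean"],
            tumor_size_sd=d["tumor_size_mm"]["sd"],
            age_mean=d["age_years"]["mean"],
            age_sd=d["age_years"]["sd"],
            ki67_mean=d["ki67_percent"]["mean"],
            ki67_sd=d["ki67_percent"]["sd"],
            n_tumor_size=d["tumor_size_mm"]["n"],
            n_age=d["age_years"]["n"],
            n_ki67=d["ki67_percent"]["n"],
        )


@dataclass(frozen=True)
class EncodedInput:
    """An ordered numeric input vector for one model variant."""

    variant: Variant
    values: np.ndarray
    source_mask: tuple  # names of the 10 variables that contributed

    def __post_init__(self) -> None:
        if len(self.values) != self.variant.input_dim:
            raise EncodingError(
                f"variant {self.variant.value} expects {self.variant.input_dim} "
                f"values, got {len(self.values)}"
            )


def _mean_sd(values: Sequence[float], name: str) -> tuple:
    vals = np.asarray([v for v in values if v is not None], dtype=float)
    if vals.size < 2 or np.unique(vals).size < 2:
        raise InvalidRecordError(
            f"need >=2 distinct non-missing values of {name} to fit normalization"
        )
    sd = float(np.std(vals, ddof=1))
    if sd <= 0:
        raise InvalidRecordError(f"{name} has zero standard deviation")
    return float(np.mean(vals)), sd, int(vals.size)


def fit_normalization(records: Iterable[PatientRecord]) -> NormalizationStats:
    """Fit standardization statistics on a training cohort.

    Means and sample (n-1) standard deviations are computed per continuous
    variable over its non-missing values.
    """
    records = list(records)
    if not records:
        raise InvalidRecordError("cannot fit normalization on an empty cohort")
    size_m, size_s, n_size = _mean_sd([r.tumor_size_mm for r in records], "tumor_size")
    age_m, age_s, n_age = _mean_sd([r.age_years for r in records], "age")
    ki_m, ki_s, n_ki = _mean_sd([r.ki67_percent for r in records], "ki67")
    return NormalizationStats(
        tumor_size_mean=size_m,
        tumor_size_sd=size_s,
        age_mean=age_m,
        age_sd=age_s,
        ki67_mean=ki_m,
        ki67_sd=ki_s,
        n_tumor_size=n_size,
        n_age=n_age,
        n_ki67=n_ki,
    )


def encode_record(
    record: PatientRecord,
    stats: NormalizationStats,
    variant: Variant,
    vi_value: Optional[float] = None,
) -> EncodedInput:
    """Encode a record into the fixed input vector of ``variant``.

    Canonical ordering: standardized tumor size; VI (N0 variants only);
    multifocality; ER (full only); histological type one-hot (NST, ILC,
    other); PR (full only); detection (screening = 1); standardized age;
    localization one-hot (central, UIQ, UOQ, LIQ, LOQ); standardized Ki67
    (full only).

    ``vi_value`` supplies an imputed VI probability in [0, 1] for the N0
    variants when the record's observed VI is missing.
    """

    def require(cond: bool, name: str) -> None:
        if not cond:
            raise EncodingError(
                f"{record.patient_id}: variable {name!r} required by variant "
                f"{variant.value} is missing"
            )

    require(record.multifocality is not None, "multifocality")
    values: list = []
    mask: list = []

    values.append((record.tumor_size_mm - stats.tumor_size_mean) / stats.tumor_size_sd)
    mask.append("tumor_size")

    if variant.uses_vi:
        if vi_value is not None:
            if not (0.0 <= vi_value <= 1.0):
                raise EncodingError(
                    f"{record.patient_id}: imputed VI value {vi_value} outside [0, 1]"
                )
            values.append(float(vi_value))
        else:
            require(record.vi is not None, "vi")
            values.append(1.0 if record.vi else 0.0)
        mask.append("vi")

    values.append(1.0 if record.multifocality else 0.0)
    mask.append("multifocality")

    if variant.uses_receptors:
        require(record.er is not None, "er")
        values.append(1.0 if record.er else 0.0)
        mask.append("er")

    onehot = [0.0, 0.0, 0.0]
    onehot[HISTOLOGICAL_TYPES.index(record.histological_type)] = 1.0
    values.extend(onehot)
    mask.append("histological_type")

    if variant.uses_receptors:
        require(record.pr is not None, "pr")
        values.append(1.0 if record.pr else 0.0)
        mask.append("pr")

    values.append(1.0 if record.detection_mode == "screening" else 0.0)
    mask.append("detection_mode")

    values.append((record.age_years - stats.age_mean) / stats.age_sd)
    mask.append("age")

    quadrant = record.localization
    loc = [1.0 if quadrant is q else 0.0 for q in LOCALIZATION_ORDER]
    values.extend(loc)
    mask.append("localization")

    if variant.uses_receptors:
        require(record.ki67_percent is not None, "ki67")
        values.append((record.ki67_percent - stats.ki67_mean) / stats.ki67_sd)
        mask.append("ki67")

    return EncodedInput(
        variant=variant, values=np.asarray(values, dtype=float), source_mask=tuple(mask)
    )


# ---------------------------------------------------------------------------
# Cohort CSV interface
# ---------------------------------------------------------------------------

CSV_COLUMNS = (
    "patient_id",
    "age_years",
    "detection_mode",
    "tumor_size_mm",
    "multifocality",
    "histological_type",
    "laterality",
    "position",
    "vi",
    "er",
    "pr",
    "ki67_percent",
    "nodal_status",
)

_BINARY_TOKENS = {
    "multifocality": {"present": True, "absent": False},
    "vi": {"present": True, "absent": False},
    "er": {"positive": True, "negative": False},
    "pr": {"positive": True, "negative": False},
}


def _parse_cell(row_no: int, name: str, raw: str):
    raw = raw.strip()
    if raw == "":
        return None
    if name in _BINARY_TOKENS:
        try:
            return _BINARY_TOKENS[name][raw]
        except KeyError:
            raise CohortCSVError(
                f"row {row_no}: invalid {name} value {raw!r}"
            ) from None
    if name in ("age_years", "tumor_size_mm", "ki67_percent"):
        try:
            return float(raw)
        except ValueError:
            raise CohortCSVError(f"row {row_no}: non-numeric {name} {raw!r}") from None
    if name == "position":
        if raw == "central":
            return "central"
        try:
            return float(raw)
        except ValueError:
            raise CohortCSVError(f"row {row_no}: invalid position {raw!r}") from None
    if name == "nodal_status":
        if raw in ("N+", "Npos"):
            return "N+"
        if raw == "N0":
            return "N0"
        if raw == "unknown":
            return None
        raise CohortCSVError(f"row {row_no}: invalid nodal_status {raw!r}")
    return raw


def read_cohort_csv(path) -> list:
    """Read and validate a cohort CSV; raises :class:`CohortCSVError` with the
    offending row number on any malformed cell."""
    records = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or set(CSV_COLUMNS) - set(reader.fieldnames):
            missing = sorted(set(CSV_COLUMNS) - set(reader.fieldnames or ()))
            raise CohortCSVError(f"missing columns: {', '.join(missing)}")
        for row_no, row in enumerate(reader, start=2):
            kwargs = {c: _parse_cell(row_no, c, row[c] or "") for c in CSV_COLUMNS}
            for required in ("patient_id", "age_years", "detection_mode",
                             "tumor_size_mm", "histological_type", "position"):
                if kwargs[required] is None:
                    raise CohortCSVError(f"row {row_no}: empty {required}")
            try:
                records.append(PatientRecord(**kwargs))
            except InvalidRecordError as exc:
                raise CohortCSVError(f"row {row_no}: {exc}") from exc
    return records


def _format_cell(name: str, value) -> str:
    if value is None:
        return ""
    if name in _BINARY_TOKENS:
        tokens = {v: k for k, v in _BINARY_TOKENS[name].items()}
        return tokens[value]
    if isinstance(value, float):
        return repr(value)  # shortest string that round-trips the double
    return str(value)


def write_cohort_csv(records: Iterable[PatientRecord], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(CSV_COLUMNS)
        for r in records:
            writer.writerow([_format_cell(c, getattr(r, c)) for c in CSV_COLUMNS])
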