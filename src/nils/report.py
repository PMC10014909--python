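"""Structured risk-communication payload for one prediction.

Mirrors the elements of the interactive display: the numeric probability of
healthy nodes (full precision plus an integer-percent display rounding), the
classification against the routed cut-point with its icon semantics, the
background distribution of the development population with the patient's
vertical-line position, and a tailored message with disclaimer.  The
classification always derives from the unrounded probability, so display
rounding can never flip it.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from typing import List, Optional

from .cohort import PatientRecord
from .workflow import ModelRegistry, PredictionResult, predict_n0

__all__ = ["RiskReportPayload", "build_risk_report"]


@dataclass
class RiskReportPayload:
    patient_id: str
    p_n0: float  # full precision
    display_percent: int  # rounded for the interface
    classification: str  # predict_N0 | predict_Npos
    icon: str  # green (at/above cut-point) | red (below)
    cutpoint: float
    pathway: str
    imputed_vi: Optional[float]
    imputer_key: Optional[str]
    background_key: str
    background_grid: List[float]
    background_density: List[float]
    patient_line_position: float  # equals p_n0, for the vertical marker
    message: str

    def to_dict(self) -> dict:
        return asdict(self)


def build_risk_report(
    registry: ModelRegistry,
    record: PatientRecord,
    result: Optional[PredictionResult] = None,
) -> RiskReportPayload:
    """Assemble the display payload for one record (predicting if needed)."""
    if result is None:
        result = predict_n0(registry, record)
    bg = registry.backgrounds[result.background_ref]
    return RiskReportPayload(
        patient_id=record.patient_id,
        p_n0=result.p_n0,
        display_percent=round(100.0 * result.p_n0),
        classification=result.classification,
        icon="green" if result.classification == "predict_N0" else "red",
        cutpoint=result.cutpoint_used,
        pathway=result.pathway,
        imputed_vi=result.imputed_vi,
        imputer_key=result.imputer_key,
        background_key=result.background_ref,
        background_grid=list(map(float, bg.grid)),
        background_density=list(map(float, bg.density)),
        patient_line_position=result.p_n0,
        message=result.message,
    )
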