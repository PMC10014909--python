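"""The deployable staging tool: routing, VI imputation, prediction, registry.

Workflow (four pathways): a record with observed VI and complete ER/PR/Ki67
goes straight to the full N0 model; missing ER/PR/Ki67 routes to the reduced
N0 model; missing VI is first imputed by one of two VI sub-models (full or
reduced, chosen by the same ER/PR/Ki67 rule) and the imputed probability is
fed into the N0 model's VI input slot (soft imputation by default).

``build_registry`` assembles the complete deployable artifact from a labeled
cohort: the two VI imputation ensembles, the two N0 ensembles with
weight-decay selected by repeated 5-fold CV, one FNR-constrained cut-point
per N0 model, and the two smoothed background distributions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .background import SmoothedDistribution, smooth_probabilities
from .cohort import (
    NormalizationStats,
    PatientRecord,
    Variant,
    encode_record,
    fit_normalization,
)
from .ensemble import EnsembleConfig, EnsembleModel, ensemble_predict, train_ensemble
from .exceptions import IneligibleRecordError, NilsError
from .metrics import (
    classification_metrics,
    confusion_at_cutoff,
    hosmer_lemeshow,
    roc_auc,
    select_cutoff_max_fnr,
)
from .model_selection import CVConfig, ValidationList, select_weight_decay

__all__ = [
    "RouteDecision",
    "PredictionResult",
    "BuildConfig",
    "ModelRegistry",
    "ConcordanceReport",
    "route",
    "impute_vi",
    "predict_n0",
    "build_registry",
    "concordance_check",
]

REGISTRY_FORMAT_VERSION = "1.0"

#: tailored message templates, keyed by (classification, has imputed VI)
MESSAGE_TEMPLATES = {
    ("predict_N0", False): (
        "The estimated probability of healthy axillary lymph nodes is {pct}%, "
        "at or above the decision cut-point of {cut}%. The tool supports "
        "considering omission of sentinel lymph node biopsy. This estimate is "
        "for research use and does not replace clinical judgement."
    ),
    ("predict_N0", True): (
        "The estimated probability of healthy axillary lymph nodes is {pct}% "
        "(vascular invasion was not reported and has been estimated by the "
        "tool), at or above the decision cut-point of {cut}%. The tool "
        "supports considering omission of sentinel lymph node biopsy. This "
        "estimate is for research use and does not replace clinical judgement."
    ),
    ("predict_Npos", False): (
        "The estimated probability of healthy axillary lymph nodes is {pct}%, "
        "below the decision cut-point of {cut}%. Surgical axillary staging "
        "remains indicated. This estimate is for research use and does not "
        "replace clinical judgement."
    ),
    ("predict_Npos", True): (
        "The estimated probability of healthy axillary lymph nodes is {pct}% "
        "(vascular invasion was not reported and has been estimated by the "
        "tool), below the decision cut-point of {cut}%. Surgical axillary "
        "staging remains indicated. This estimate is for research use and "
        "does not replace clinical judgement."
    ),
}


@dataclass(frozen=True)
class RouteDecision:
    vi_imputer: Optional[Variant]  # None, VI_FULL or VI_REDUCED
    n0_model: Variant  # N0_FULL or N0_REDUCED
    pathway: str  # full | full_vi_imputed | reduced | reduced_vi_imputed


@dataclass
class PredictionResult:
    p_n0: float
    pathway: str
    imputed_vi: Optional[float]
    imputer_key: Optional[str]
    cutpoint_used: float
    classification: str  # predict_N0 | predict_Npos
    background_ref: str  # full | reduced
    message: str

    def __post_init__(self) -> None:
        expected = "predict_N0" if self.p_n0 >= self.cutpoint_used else "predict_Npos"
        if self.classification != expected:
            raise NilsError("classification inconsistent with cut-point rule")


def route(record: PatientRecord) -> RouteDecision:
    """Fig-1-style routing over the missingness pattern of VI/ER/PR/Ki67.

    Raises :class:`IneligibleRecordError` if a mandatory variable is missing.
    """
    if record.multifocality is None:
        raise IneligibleRecordError(
            f"{record.patient_id}: mandatory variable 'multifocality' is missing"
        )
    receptors_complete = (
        record.er is not None
        and record.pr is not None
        and record.ki67_percent is not None
    )
    vi_present = record.vi is not None
    if vi_present and receptors_complete:
        return RouteDecision(None, Variant.N0_FULL, "full")
    if vi_present:
        return RouteDecision(None, Variant.N0_REDUCED, "reduced")
    if receptors_complete:
        return RouteDecision(Variant.VI_FULL, Variant.N0_FULL, "full_vi_imputed")
    return RouteDecision(Variant.VI_REDUCED, Variant.N0_REDUCED, "reduced_vi_imputed")


@dataclass
class BuildConfig:
    seed: int = 0
    lambda_grid: Tuple[float, ...] = (0.0001, 0.001, 0.01, 0.1, 1.0)
    ensemble_repeats: int = 10  # final ensembles: 3 x repeats members
    cv_k: int = 5
    cv_repeats: int = 5
    cv_ensemble_repeats: int = 10  # member rounds inside each CV fold
    hidden_dim: int = 10
    max_iterations: int = 500
    convergence_tolerance: float = 1e-8
    init_scale: float = 0.5
    max_fnr: float = 0.10
    background_bandwidth: float = 0.5
    background_grid_size: int = 512
    vi_hard_threshold: Optional[float] = None  # None = soft imputation
    version: str = "0.1.0"


@dataclass
class ModelRegistry:
    """The deployable tool: 4 ensembles, 2 cut-points, 2 background curves."""

    models: Dict[Variant, EnsembleModel]
    cutpoints: Dict[str, float]  # keys: full, reduced
    backgrounds: Dict[str, SmoothedDistribution]
    normalization: NormalizationStats
    version: str = "0.1.0"
    provenance: dict = field(default_factory=dict)
    vi_hard_threshold: Optional[float] = None

    def __post_init__(self) -> None:
        if set(self.models) != set(Variant):
            raise NilsError("registry must contain all four model variants")
        for key in ("full", "reduced"):
            c = self.cutpoints.get(key)
            if c is None or not (0.0 < c < 1.0):
                raise NilsError(f"cut-point {key!r} must be in (0, 1)")
            if key not in self.backgrounds:
                raise NilsError(f"background distribution {key!r} missing")

    def to_json_dict(self) -> dict:
        return {
            "format_version": REGISTRY_FORMAT_VERSION,
            "version": self.version,
            "normalization": self.normalization.to_dict(),
            "models": {v.value: m.to_dict() for v, m in self.models.items()},
            "cutpoints": dict(self.cutpoints),
            "backgrounds": {k: b.to_dict() for k, b in self.backgrounds.items()},
            "provenance": self.provenance,
            "vi_hard_threshold": self.vi_hard_threshold,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_json_dict(), sort_keys=True)

    @classmethod
    def from_json_dict(cls, d: dict) -> "ModelRegistry":
        if d.get("format_version") != REGISTRY_FORMAT_VERSION:
            raise NilsError(
                f"unsupported registry format {d.get('format_version')!r}; "
                f"expected {REGISTRY_FORMAT_VERSION}"
            )
        return cls(
            models={Variant(k): EnsembleModel.from_dict(m) for k, m in d["models"].items()},
            cutpoints=dict(d["cutpoints"]),
            backgrounds={
                k: SmoothedDistribution.from_dict(b) for k, b in d["backgrounds"].items()
            },
            normalization=NormalizationStats.from_dict(d["normalization"]),
            version=d.get("version", "0.1.0"),
            provenance=d.get("provenance", {}),
            vi_hard_threshold=d.get("vi_hard_threshold"),
        )

    def save(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_json())

    @classmethod
    def load(cls, path) -> "ModelRegistry":
        with open(path) as fh:
            return cls.from_json_dict(json.load(fh))


def impute_vi(registry: ModelRegistry, record: PatientRecord) -> float:
    """Probability that VI is present, from the routed imputation sub-model."""
    if record.vi is not None:
        raise NilsError(f"{record.patient_id}: VI is present; nothing to impute")
    decision = route(record)
    imputer = registry.models[decision.vi_imputer]
    enc = encode_record(record, registry.normalization, decision.vi_imputer)
    return ensemble_predict(imputer, enc)


def predict_n0(registry: ModelRegistry, record: PatientRecord) -> PredictionResult:
    """Route, impute VI if needed, predict p(N0) and classify."""
    decision = route(record)
    vi_value = None
    imputed = None
    imputer_key = None
    if decision.vi_imputer is not None:
        imputed = impute_vi(registry, record)
        imputer_key = decision.vi_imputer.value
        if registry.vi_hard_threshold is not None:
            vi_value = 1.0 if imputed >= registry.vi_hard_threshold else 0.0
        else:
            vi_value = imputed
    enc = encode_record(record, registry.normalization, decision.n0_model, vi_value=vi_value)
    p = ensemble_predict(registry.models[decision.n0_model], enc)
    key = "full" if decision.n0_model is Variant.N0_FULL else "reduced"
    cut = registry.cutpoints[key]
    classification = "predict_N0" if p >= cut else "predict_Npos"
    message = MESSAGE_TEMPLATES[(classification, imputed is not None)].format(
        pct=round(100.0 * p), cut=round(100.0 * cut)
    )
    return PredictionResult(
        p_n0=p,
        pathway=decision.pathway,
        imputed_vi=imputed,
        imputer_key=imputer_key,
        cutpoint_used=cut,
        classification=classification,
        background_ref=key,
        message=message,
    )


def predict_cohort(registry: ModelRegistry, records: Sequence[PatientRecord]) -> np.ndarray:
    """Vector of p(N0) for a sequence of eligible records."""
    return np.asarray([predict_n0(registry, r).p_n0 for r in records], dtype=float)


def _derived_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def _training_vi_fill(
    registry_models: Dict[Variant, EnsembleModel],
    stats: NormalizationStats,
    records: Sequence[PatientRecord],
) -> Dict[str, float]:
    """Impute VI for training records, mirroring deployment routing."""
    fill: Dict[str, float] = {}
    for r in records:
        if r.vi is not None:
            continue
        receptors = r.er is not None and r.pr is not None and r.ki67_percent is not None
        variant = Variant.VI_FULL if receptors else Variant.VI_REDUCED
        enc = encode_record(r, stats, variant)
        fill[r.patient_id] = ensemble_predict(registry_models[variant], enc)
    return fill


def build_registry(
    records: Sequence[PatientRecord], config: BuildConfig
) -> Tuple[ModelRegistry, dict]:
    """Train the full four-model registry from a labeled cohort.

    Order: the two VI imputation ensembles are trained first (on records
    with observed VI, target = VI); their predictions fill missing VI for
    N0-model training, mirroring deployment.  Weight decay is selected per
    model by repeated stratified 5-fold CV; the two N0 cut-points come from
    FNR-constrained search on the winners' fused validation lists, and the
    background distributions smooth the same lists.
    """
    records = list(records)
    for r in records:
        if r.nodal_status is None:
            raise NilsError(f"{r.patient_id}: unlabeled record in training cohort")
        if r.multifocality is None:
            raise IneligibleRecordError(
                f"{r.patient_id}: mandatory variable 'multifocality' missing"
            )
    labels_n0 = np.asarray([r.is_n0 for r in records], dtype=float)
    if labels_n0.min() == labels_n0.max():
        raise NilsError("training cohort must contain both N0 and N+ patients")
    stats = fit_normalization(records)

    models: Dict[Variant, EnsembleModel] = {}
    report: dict = {"models": {}, "seed": config.seed, "n_records": len(records)}
    stage = {"vi_full": 0, "vi_reduced": 1, "n0_full": 2, "n0_reduced": 3}

    def build_one(
        variant: Variant,
        pool: List[PatientRecord],
        labels: np.ndarray,
        vi_fill: Optional[Dict[str, float]],
    ) -> ValidationList:
        s = stage[variant.value]
        cv_cfg = CVConfig(
            k=config.cv_k,
            repeats=config.cv_repeats,
            seed=_derived_seed(config.seed, s, 0),
            ensemble_repeats=config.cv_ensemble_repeats,
            hidden_dim=config.hidden_dim,
            max_iterations=config.max_iterations,
            convergence_tolerance=config.convergence_tolerance,
            init_scale=config.init_scale,
        )
        selection = select_weight_decay(
            pool, labels, variant, config.lambda_grid, cv_cfg, stats=stats, vi_fill=vi_fill
        )
        lam = selection.lambda_star
        models[variant] = train_ensemble(
            pool,
            labels,
            variant,
            EnsembleConfig(
                repeats=config.ensemble_repeats,
                lambda_decay=lam,
                hidden_dim=config.hidden_dim,
                max_iterations=config.max_iterations,
                convergence_tolerance=config.convergence_tolerance,
                init_scale=config.init_scale,
                seed=_derived_seed(config.seed, s, 1),
            ),
            stats=stats,
            vi_fill=vi_fill,
        )
        final = selection.final_lists[lam]
        auc, lo, hi = roc_auc(final.labels, final.probs)
        chi2, df, pval = hosmer_lemeshow(final.labels, final.probs)
        report["models"][variant.value] = {
            "lambda_star": lam,
            "lambda_table": selection.table.to_dict("records"),
            "n_training": len(pool),
            "auc": auc,
            "auc_ci": [lo, hi],
            "hosmer_lemeshow": {"chi2": chi2, "df": df, "p_value": pval,
                                "replication": "single_final_list"},
            "cv_seed": cv_cfg.seed,
        }
        return final

    # --- VI imputation sub-models: records with observed VI, target = VI ---
    vi_pool = [r for r in records if r.vi is not None]
    vi_labels = np.asarray([r.vi for r in vi_pool], dtype=float)
    if vi_pool and vi_labels.min() != vi_labels.max():
        for variant in (Variant.VI_FULL, Variant.VI_REDUCED):
            build_one(variant, vi_pool, vi_labels, vi_fill=None)
    else:
        raise NilsError("need observed VI of both classes to train the imputers")

    # --- fill missing VI for N0-model training, mirroring deployment ---
    vi_fill = _training_vi_fill(models, stats, records)

    # --- N0 models, cut-points, backgrounds ---
    cutpoints: Dict[str, float] = {}
    backgrounds: Dict[str, SmoothedDistribution] = {}
    for variant, key in ((Variant.N0_FULL, "full"), (Variant.N0_REDUCED, "reduced")):
        final = build_one(variant, records, labels_n0, vi_fill=vi_fill)
        cut, counts = select_cutoff_max_fnr(final.labels, final.probs, config.max_fnr)
        cutpoints[key] = cut
        backgrounds[key] = smooth_probabilities(
            final.probs,
            bandwidth=config.background_bandwidth,
            grid_size=config.background_grid_size,
            model_key=variant.value,
        )
        report["models"][variant.value]["cutpoint"] = cut
        report["models"][variant.value]["confusion_at_cutpoint"] = {
            "TP": counts.tp, "TN": counts.tn, "FP": counts.fp, "FN": counts.fn,
        }
        report["models"][variant.value]["metrics_at_cutpoint"] = classification_metrics(counts)

    registry = ModelRegistry(
        models=models,
        cutpoints=cutpoints,
        backgrounds=backgrounds,
        normalization=stats,
        version=config.version,
        provenance={
            "build_seed": config.seed,
            "lambda_per_model": {
                v.value: report["models"][v.value]["lambda_star"] for v in Variant
            },
            "ensemble_repeats": config.ensemble_repeats,
            "cv": {
                "k": config.cv_k,
                "repeats": config.cv_repeats,
                "ensemble_repeats": config.cv_ensemble_repeats,
            },
            "n_vi_training_records": len(vi_pool),
            "n_vi_imputed_for_training": len(vi_fill),
        },
        vi_hard_threshold=config.vi_hard_threshold,
    )
    return registry, report


@dataclass
class ConcordanceReport:
    n_evaluated: int
    n_matched: int
    n_mismatched: int
    n_ineligible: int
    deltas: List[dict]  # per evaluated record: patient_id, delta_p, matched

    def to_dict(self) -> dict:
        return {
            "n_evaluated": self.n_evaluated,
            "n_matched": self.n_matched,
            "n_mismatched": self.n_mismatched,
            "n_ineligible": self.n_ineligible,
            "deltas": self.deltas,
        }


def concordance_check(
    registry: ModelRegistry,
    records: Sequence[PatientRecord],
    tolerance: float = 1e-8,
    reference_dict: Optional[dict] = None,
) -> ConcordanceReport:
    """Compare the full prediction path against an independent reference
    recomputation over the serialized parameters.

    A record matches iff |delta p| <= ``tolerance`` and the pathway and
    cut-point agree exactly; ineligible records (missing mandatory input)
    are counted, not matched.  ``reference_dict`` defaults to the registry's
    own serialization; passing another copy's parameters lets the harness
    detect drift between a deployed instance and the reference algorithm.
    """
    from . import reference  # deferred: keeps the reference path standalone

    registry_dict = reference_dict if reference_dict is not None else registry.to_json_dict()
    matched = mismatched = ineligible = 0
    deltas: List[dict] = []
    for rec in records:
        try:
            result = predict_n0(registry, rec)
        except IneligibleRecordError:
            ineligible += 1
            continue
        ref_p, ref_cut, ref_pathway = reference.reference_predict(registry_dict, rec)
        delta = abs(result.p_n0 - ref_p)
        ok = (
            delta <= tolerance
            and result.pathway == ref_pathway
            and result.cutpoint_used == ref_cut
        )
        matched += int(ok)
        mismatched += int(not ok)
        deltas.append(
            {"patient_id": rec.patient_id, "delta_p": float(delta), "matched": bool(ok)}
        )
    return ConcordanceReport(
        n_evaluated=matched + mismatched,
        n_matched=matched,
        n_mismatched=mismatched,
        n_ineligible=ineligible,
        deltas=deltas,
    )
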