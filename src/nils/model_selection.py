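"""Weight-decay selection by repeated stratified k-fold cross-validation.

A full member-subsampled ensemble is trained inside every fold; the k
out-of-fold prediction sets of a repeat are concatenated into one fused
validation list covering every patient once, and the ``repeats`` fused lists
are averaged per patient into the final list from which all performance is
reported.  The decay parameter with the best final-list AUC wins (ties
toward the larger, i.e. more regularized, value).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold

from .cohort import NormalizationStats, PatientRecord, Variant, fit_normalization
from .ensemble import (
    EnsembleConfig,
    encode_matrix,
    ensemble_predict,
    observed_marginals,
    train_ensemble,
)
from .exceptions import NilsError, TrainingError
from .metrics import roc_auc

__all__ = ["ValidationList", "CVConfig", "CVResult", "repeated_cv",
           "SelectionResult", "select_weight_decay"]


@dataclass
class ValidationList:
    """Per-patient out-of-fold predictions (or their across-repeat average)."""

    patient_ids: tuple
    labels: np.ndarray  # the 0/1 training target (is-N0 or VI-present)
    probs: np.ndarray
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise NilsError("validation list must cover every patient exactly once")
        if np.any(self.probs <= 0) or np.any(self.probs >= 1):
            raise NilsError("validation probabilities must be inside (0, 1)")

    @property
    def n(self) -> int:
        return len(self.patient_ids)


@dataclass
class CVConfig:
    k: int = 5
    repeats: int = 5
    seed: int = 0
    ensemble_repeats: int = 10  # member rounds of each fold's ensemble
    hidden_dim: int = 10
    max_iterations: int = 500
    convergence_tolerance: float = 1e-8
    init_scale: float = 0.5


@dataclass
class FoldResult:
    repeat_index: int
    fold_index: int
    n_validation: int
    auc: float


@dataclass
class CVResult:
    fold_results: List[FoldResult]
    repeat_lists: List[ValidationList]
    final_list: ValidationList


def _derived_seed(seed: int, *key: int) -> int:
    ss = np.random.SeedSequence(seed, spawn_key=tuple(key))
    return int(ss.generate_state(1)[0] % (2**31))


def repeated_cv(
    records: Sequence[PatientRecord],
    labels: Sequence,
    variant: Variant,
    lambda_decay: float,
    config: CVConfig,
    stats: Optional[NormalizationStats] = None,
    vi_fill: Optional[Dict[str, float]] = None,
) -> CVResult:
    """Repeated stratified k-fold CV of the full ensemble pipeline.

    Returns the k x repeats fold results, one fused validation list per
    repeat, and the final per-patient average list.
    """
    records = list(records)
    y = np.asarray(labels, dtype=float)
    if config.k < 2:
        raise NilsError("k must be >= 2")
    _, counts = np.unique(y, return_counts=True)
    if len(counts) < 2 or counts.min() < config.k:
        raise NilsError("each class needs at least k records")
    if stats is None:
        stats = fit_normalization(records)
    ids = tuple(r.patient_id for r in records)
    fold_results: List[FoldResult] = []
    repeat_lists: List[ValidationList] = []
    for rep in range(config.repeats):
        skf = StratifiedKFold(
            n_splits=config.k, shuffle=True, random_state=_derived_seed(config.seed, rep)
        )
        probs = np.empty(len(records))
        for fold, (tr, va) in enumerate(skf.split(np.zeros(len(records)), y)):
            train_records = [records[i] for i in tr]
            model = train_ensemble(
                train_records,
                y[tr],
                variant,
                EnsembleConfig(
                    repeats=config.ensemble_repeats,
                    lambda_decay=lambda_decay,
                    hidden_dim=config.hidden_dim,
                    max_iterations=config.max_iterations,
                    convergence_tolerance=config.convergence_tolerance,
                    init_scale=config.init_scale,
                    seed=_derived_seed(config.seed, rep, fold),
                ),
                stats=stats,
                vi_fill=vi_fill,
            )
            # out-of-fold records may still need hot-deck for *_full variants
            rng = np.random.default_rng(
                np.random.SeedSequence(config.seed, spawn_key=(rep, fold, 2))
            )
            Xva = encode_matrix(
                [records[i] for i in va],
                variant,
                stats,
                vi_fill=vi_fill,
                rng=rng,
                marginals=observed_marginals(train_records),
            )
            pva = ensemble_predict(model, Xva)
            probs[va] = pva
            fold_results.append(
                FoldResult(
                    repeat_index=rep,
                    fold_index=fold,
                    n_validation=len(va),
                    auc=roc_auc(y[va].astype(bool), pva)[0],
                )
            )
        repeat_lists.append(
            ValidationList(
                patient_ids=ids,
                labels=y.astype(bool),
                probs=probs.copy(),
                metadata={
                    "variant": variant.value,
                    "lambda_decay": lambda_decay,
                    "k": config.k,
                    "repeat": rep,
                    "seed": config.seed,
                },
            )
        )
    final = ValidationList(
        patient_ids=ids,
        labels=y.astype(bool),
        probs=np.mean([vl.probs for vl in repeat_lists], axis=0),
        metadata={
            "variant": variant.value,
            "lambda_decay": lambda_decay,
            "k": config.k,
            "repeats": config.repeats,
            "seed": config.seed,
        },
    )
    return CVResult(fold_results=fold_results, repeat_lists=repeat_lists, final_list=final)


@dataclass
class SelectionResult:
    lambda_star: float
    table: pd.DataFrame  # columns: lambda_decay, auc
    final_lists: Dict[float, ValidationList]


def select_weight_decay(
    records: Sequence[PatientRecord],
    labels: Sequence,
    variant: Variant,
    lambda_grid: Sequence[float],
    config: CVConfig,
    stats: Optional[NormalizationStats] = None,
    vi_fill: Optional[Dict[str, float]] = None,
) -> SelectionResult:
    """Pick the weight-decay value with the best fused-validation AUC.

    All grid values share the same seeded fold partitions (a paired
    comparison), so the result is invariant to grid order; ties break toward
    the larger decay.
    """
    grid = sorted(set(float(l) for l in lambda_grid))
    if not grid:
        raise NilsError("lambda grid must be non-empty")
    if any(l < 0 for l in grid):
        raise TrainingError("lambda values must be nonnegative")
    rows = []
    lists: Dict[float, ValidationList] = {}
    for lam in grid:
        cv = repeated_cv(records, labels, variant, lam, config, stats=stats, vi_fill=vi_fill)
        fl = cv.final_list
        rows.append({"lambda_decay": lam, "auc": roc_auc(fl.labels, fl.probs)[0]})
        lists[lam] = fl
    table = pd.DataFrame(rows)
    return SelectionResult(
        lambda_star=pick_lambda_star(table), table=table, final_lists=lists
    )


def pick_lambda_star(table: pd.DataFrame) -> float:
    """Best-AUC decay value from a performance table; ties toward larger."""
    best_auc = table["auc"].max()
    return float(table.loc[table["auc"] == best_auc, "lambda_decay"].max())
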