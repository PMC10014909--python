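"""Ensembles of MLPs built by stratified three-part subsampling.

Each member network is trained on a "leave-one-part-out" union of two of
three class-stratified, (near-)equal-size parts of the training data.  The
three-part split is repeated ``repeats`` times (default 10), giving
3 x repeats = 30 members.  The ensemble prediction is the arithmetic mean of
the member outputs.

Training-time missingness handling: records used to train a *_full variant
may lack ER/PR/Ki67; each member draws replacements from the variable's
observed marginal (hot-deck), re-drawn per member with its own seeded
generator.  Missing VI for the N0 variants must be pre-filled via
``vi_fill`` (the imputation sub-models; see :mod:`nils.workflow`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np

from .cohort import EncodedInput, NormalizationStats, PatientRecord, Variant, encode_record, fit_normalization
from .exceptions import EncodingError, TrainingError
from .mlp import MLPParameters, TrainingConfig, mlp_forward, train_mlp

__all__ = [
    "MemberSubset",
    "EnsembleConfig",
    "EnsembleModel",
    "make_member_training_sets",
    "train_ensemble",
    "ensemble_predict",
    "observed_marginals",
    "encode_matrix",
]


@dataclass(frozen=True)
class MemberSubset:
    round_index: int
    left_out_part: int  # 0, 1 or 2
    indices: np.ndarray  # row indices into the training records


@dataclass
class EnsembleConfig:
    repeats: int = 10
    lambda_decay: float = 0.01
    hidden_dim: int = 10
    max_iterations: int = 500
    convergence_tolerance: float = 1e-8
    init_scale: float = 0.5
    seed: int = 0


@dataclass
class EnsembleModel:
    variant: Variant
    members: List[MLPParameters]
    normalization: NormalizationStats
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        dims = {m.input_dim for m in self.members}
        if len(dims) > 1:
            raise TrainingError("ensemble members disagree on input_dim")
        if dims and dims != {self.variant.input_dim}:
            raise TrainingError(
                f"member input_dim {dims} != variant dim {self.variant.input_dim}"
            )

    def to_dict(self) -> dict:
        return {
            "variant": self.variant.value,
            "members": [m.to_dict() for m in self.members],
            "normalization": self.normalization.to_dict(),
            "provenance": self.provenance,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "EnsembleModel":
        return cls(
            variant=Variant(d["variant"]),
            members=[MLPParameters.from_dict(m) for m in d["members"]],
            normalization=NormalizationStats.from_dict(d["normalization"]),
            provenance=d.get("provenance", {}),
        )


def make_member_training_sets(
    labels: Sequence, repeats: int = 10, seed: int = 0
) -> List[MemberSubset]:
    """Stratified 3-split subsampling: 3 x ``repeats`` member training sets.

    Per round the records are split by class into three parts whose per-class
    sizes differ from n_class/3 by at most 1 (remainders assigned in seeded
    shuffle order); each part is left out once, so every record appears in
    exactly two of the round's three subsets.
    """
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if repeats < 0:
        raise TrainingError("repeats must be nonnegative")
    if repeats and (len(classes) < 2 or counts.min() < 3):
        raise TrainingError("need at least 3 records per class for the 3-split")
    subsets: List[MemberSubset] = []
    for r in range(repeats):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(r,)))
        parts = [[], [], []]
        for c in classes:
            idx = np.flatnonzero(y == c)
            rng.shuffle(idx)
            for p, chunk in enumerate(np.array_split(idx, 3)):
                parts[p].append(chunk)
        parts = [np.sort(np.concatenate(chunks)) for chunks in parts]
        for left_out in range(3):
            keep = np.sort(
                np.concatenate([parts[p] for p in range(3) if p != left_out])
            )
            subsets.append(
                MemberSubset(round_index=r, left_out_part=left_out, indices=keep)
            )
    return subsets


def observed_marginals(records: Sequence[PatientRecord]) -> Dict[str, np.ndarray]:
    """Observed value pools of the four missingness-prone variables, for
    hot-deck draws."""
    return {
        "vi": np.asarray([r.vi for r in records if r.vi is not None], dtype=bool),
        "er": np.asarray([r.er for r in records if r.er is not None], dtype=bool),
        "pr": np.asarray([r.pr for r in records if r.pr is not None], dtype=bool),
        "ki67": np.asarray(
            [r.ki67_percent for r in records if r.ki67_percent is not None],
            dtype=float,
        ),
    }


def _hot_deck(record: PatientRecord, variant: Variant, rng, marginals) -> PatientRecord:
    """Fill ER/PR/Ki67 required by ``variant`` from their observed marginals."""
    if not variant.uses_receptors:
        return record
    updates = {}
    for name, attr in (("er", "er"), ("pr", "pr"), ("ki67", "ki67_percent")):
        if getattr(record, attr) is None:
            pool = marginals[name]
            if pool.size == 0:
                raise EncodingError(f"no observed values of {name} for hot-deck")
            updates[attr] = pool[rng.integers(pool.size)].item()
    return replace(record, **updates) if updates else record


def encode_matrix(
    records: Sequence[PatientRecord],
    variant: Variant,
    stats: NormalizationStats,
    vi_fill: Optional[Dict[str, float]] = None,
    rng=None,
    marginals: Optional[Dict[str, np.ndarray]] = None,
) -> np.ndarray:
    """Encode records into an (n, input_dim) design matrix.

    ``vi_fill`` maps patient_id to an imputed VI probability, used when an
    N0-variant record has missing VI.  If ``rng`` and ``marginals`` are
    given, missing ER/PR/Ki67 are hot-deck imputed; otherwise they raise.
    """
    rows = []
    for rec in records:
        if rng is not None and marginals is not None:
            rec_resolved = _hot_deck(rec, variant, rng, marginals)
        else:
            rec_resolved = rec
        vi_value = None
        if variant.uses_vi and rec.vi is None:
            if vi_fill is None or rec.patient_id not in vi_fill:
                raise EncodingError(
                    f"{rec.patient_id}: missing VI and no imputed value supplied"
                )
            vi_value = vi_fill[rec.patient_id]
        rows.append(encode_record(rec_resolved, stats, variant, vi_value=vi_value).values)
    return np.asarray(rows, dtype=float)


def _member_seed(master_seed: int, round_index: int, part: int) -> int:
    ss = np.random.SeedSequence(master_seed, spawn_key=(round_index, part))
    return int(ss.generate_state(1)[0] % (2**31))


def train_ensemble(
    records: Sequence[PatientRecord],
    labels: Sequence,
    variant: Variant,
    config: EnsembleConfig,
    stats: Optional[NormalizationStats] = None,
    vi_fill: Optional[Dict[str, float]] = None,
) -> EnsembleModel:
    """Train a 3 x ``config.repeats`` member ensemble for ``variant``.

    ``labels`` are the 0/1 training targets (N0 status for the N0 models, VI
    presence for the imputation models).  Deterministic given
    ``config.seed``: member seeds are derived per (round, part).
    """
    records = list(records)
    y = np.asarray(labels, dtype=float)
    if len(records) != y.size:
        raise TrainingError("one label per record required")
    if stats is None:
        stats = fit_normalization(records)
    marginals = observed_marginals(records)
    subsets = make_member_training_sets(y, repeats=config.repeats, seed=config.seed)
    members: List[MLPParameters] = []
    for member_index, sub in enumerate(subsets):
        mseed = _member_seed(config.seed, sub.round_index, sub.left_out_part)
        rng = np.random.default_rng(
            np.random.SeedSequence(config.seed, spawn_key=(sub.round_index, sub.left_out_part, 1))
        )
        try:
            X = encode_matrix(
                [records[i] for i in sub.indices],
                variant,
                stats,
                vi_fill=vi_fill,
                rng=rng,
                marginals=marginals,
            )
            params = train_mlp(
                X,
                y[sub.indices],
                TrainingConfig(
                    lambda_decay=config.lambda_decay,
                    max_iterations=config.max_iterations,
                    convergence_tolerance=config.convergence_tolerance,
                    init_scale=config.init_scale,
                    hidden_dim=config.hidden_dim,
                    seed=mseed,
                ),
            )
        except (EncodingError, TrainingError) as exc:
            raise type(exc)(f"member {member_index}: {exc}") from exc
        members.append(params)
    return EnsembleModel(
        variant=variant,
        members=members,
        normalization=stats,
        provenance={
            "master_seed": config.seed,
            "lambda_decay": config.lambda_decay,
            "repeats": config.repeats,
            "n_training_records": len(records),
            "member_subset_sizes": [int(s.indices.size) for s in subsets],
        },
    )


def ensemble_predict(model: EnsembleModel, encoded) -> float:
    """Mean of the member forward passes.

    ``encoded`` is an :class:`EncodedInput` (variant-checked), a vector, or
    an (n, d) batch.
    """
    if isinstance(encoded, EncodedInput):
        if encoded.variant is not model.variant:
            raise EncodingError(
                f"encoded variant {encoded.variant.value} does not match model "
                f"variant {model.variant.value}"
            )
        x = encoded.values
    else:
        x = np.asarray(encoded, dtype=float)
    preds = [mlp_forward(m, x) for m in model.members]
    return float(np.mean(preds)) if np.ndim(x) == 1 else np.mean(preds, axis=0)
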