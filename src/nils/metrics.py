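"""Discrimination, calibration, confusion accounting and cut-point search.

Conventions
-----------
* Scores are predicted probabilities of healthy nodes (p_N0); AUC is the
  tie-corrected Mann-Whitney probability that an N0 patient's p_N0 exceeds
  an N+ patient's, with a 95% DeLong confidence interval.
* For confusion counts the *positive* class is N+ (metastasis): a patient is
  "predicted positive" when classified N+ (sent to SLNB) and "predicted
  negative" when classified N0 (surgery omitted).  Classification rule:
  predict N0 iff p_N0 >= cut-point.
* The SLNB reduction rate (TN + FN)/n is the fraction of patients the tool
  classifies N0, i.e. the surgeries that could be omitted.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Callable, Dict, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .cohort import VARIABLE_NAMES
from .exceptions import NilsError, UndefinedMetricError

__all__ = [
    "ConfusionCounts",
    "roc_auc",
    "hosmer_lemeshow",
    "confusion_at_cutoff",
    "classification_metrics",
    "select_cutoff_max_fnr",
    "permutation_importance",
]


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int  # N+ classified N+
    tn: int  # N0 classified N0
    fp: int  # N0 classified N+
    fn: int  # N+ classified N0

    @property
    def n(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def _check_labels(is_n0, scores):
    y = np.asarray(is_n0, dtype=bool)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape or y.ndim != 1:
        raise NilsError("labels and scores must be equal-length 1-D arrays")
    if not np.all(np.isfinite(s)):
        raise NilsError("scores must be finite")
    if y.all() or not y.any():
        raise NilsError("both classes must be present")
    return y, s


def roc_auc(is_n0, scores) -> tuple:
    """AUC with 95% DeLong CI.

    ``is_n0`` flags the class whose probability ``scores`` estimate; the AUC
    is the concordance probability that an N0 patient's score exceeds an N+
    patient's, ties counted 1/2.
    """
    y, s = _check_labels(is_n0, scores)
    pos = s[y]  # N0
    neg = s[~y]  # N+
    m, n = pos.size, neg.size
    ranks = sps.rankdata(s)
    auc = (ranks[y].sum() - m * (m + 1) / 2.0) / (m * n)
    # DeLong structural components: placements of each score within the
    # opposite class.
    v10 = np.array([(np.sum(p > neg) + 0.5 * np.sum(p == neg)) / n for p in pos])
    v01 = np.array([(np.sum(pos > q) + 0.5 * np.sum(pos == q)) / m for q in neg])
    var = 0.0
    if m > 1:
        var += np.var(v10, ddof=1) / m
    if n > 1:
        var += np.var(v01, ddof=1) / n
    half = 1.959963984540054 * np.sqrt(var)
    return float(auc), float(max(0.0, auc - half)), float(min(1.0, auc + half))


def hosmer_lemeshow(is_event, probs, n_groups: int = 10) -> tuple:
    """Hosmer-Lemeshow chi-squared calibration statistic.

    Patients are sorted into ``n_groups`` quantile groups of predicted
    probability (ties kept together, so fewer groups may result); the
    statistic sums (observed - expected)^2 / expected over both outcome cells
    of every group, with df = groups - 2.
    """
    y = np.asarray(is_event, dtype=float)
    p = np.asarray(probs, dtype=float)
    if y.shape != p.shape or y.ndim != 1:
        raise NilsError("labels and probs must be equal-length 1-D arrays")
    if np.any(p <= 0) or np.any(p >= 1):
        raise NilsError("probabilities must be strictly inside (0, 1)")
    if y.size < n_groups:
        raise NilsError("need at least one patient per group")
    groups = pd.qcut(p, n_groups, labels=False, duplicates="drop")
    g = int(groups.max()) + 1
    chi2 = 0.0
    for k in range(g):
        sel = groups == k
        nk = int(sel.sum())
        e1 = float(p[sel].sum())
        o1 = float(y[sel].sum())
        e0 = nk - e1
        o0 = nk - o1
        if e1 <= 0 or e0 <= 0:
            raise NilsError(
                "a group has zero expected count; use fewer groups"
            )
        chi2 += (o1 - e1) ** 2 / e1 + (o0 - e0) ** 2 / e0
    df = g - 2
    # with fewer than 3 groups the statistic is still defined but carries no
    # degrees of freedom; the p-value is undefined
    pval = float(sps.chi2.sf(chi2, df)) if df >= 1 else float("nan")
    return float(chi2), int(df), pval


def confusion_at_cutoff(is_n0, p_n0, c: float) -> ConfusionCounts:
    """Counts with the decision rule: classify N0 iff p_N0 >= c."""
    y = np.asarray(is_n0, dtype=bool)
    p = np.asarray(p_n0, dtype=float)
    pred_n0 = p >= c
    return ConfusionCounts(
        tp=int(np.sum(~y & ~pred_n0)),
        tn=int(np.sum(y & pred_n0)),
        fp=int(np.sum(y & ~pred_n0)),
        fn=int(np.sum(~y & pred_n0)),
    )


def classification_metrics(counts: ConfusionCounts) -> Dict[str, float]:
    """Sensitivity, specificity, FNR and SLNB reduction rate from counts.

    sensitivity = TP/(TP+FN); specificity = TN/(TN+FP); FNR = FN/(FN+TP);
    reduction = (TN+FN)/n.
    """
    out: Dict[str, float] = {}
    if counts.tp + counts.fn == 0:
        raise UndefinedMetricError("sensitivity/fnr undefined: no N+ patients")
    if counts.tn + counts.fp == 0:
        raise UndefinedMetricError("specificity undefined: no N0 patients")
    if counts.n == 0:
        raise UndefinedMetricError("slnb_reduction_rate undefined: empty cohort")
    out["sensitivity"] = counts.tp / (counts.tp + counts.fn)
    out["specificity"] = counts.tn / (counts.tn + counts.fp)
    out["fnr"] = counts.fn / (counts.fn + counts.tp)
    out["slnb_reduction_rate"] = (counts.tn + counts.fn) / counts.n
    return out


def select_cutoff_max_fnr(is_n0, p_n0, max_fnr: float = 0.10) -> tuple:
    """FNR-constrained cut-point: among candidates with FNR <= ``max_fnr``,
    the one maximizing the SLNB reduction rate (ties toward the higher
    cut-off).

    Candidates are the midpoints between consecutive distinct probabilities
    plus sentinels below the minimum and above the maximum; the
    all-predict-N+ sentinel has FN = 0, so the search is always feasible.
    """
    y, p = _check_labels(is_n0, p_n0)
    u = np.unique(p)
    candidates = np.concatenate(
        [[u[0] / 2.0], (u[:-1] + u[1:]) / 2.0, [(u[-1] + 1.0) / 2.0]]
    )
    n_pos = int(np.sum(~y))  # N+
    best = None
    for c in candidates:
        fn = int(np.sum(~y & (p >= c)))
        fnr = fn / n_pos
        if fnr > max_fnr:
            continue
        tn = int(np.sum(y & (p >= c)))
        reduction = (tn + fn) / y.size
        # ties toward the higher cut-off: >= on equal reduction
        if best is None or reduction > best[1] or (reduction == best[1] and c > best[0]):
            best = (float(c), reduction)
    cut = best[0]
    return cut, confusion_at_cutoff(y, p, cut)


def permutation_importance(
    predict_fn: Callable[[Sequence], np.ndarray],
    records: Sequence,
    seed: int = 0,
    n_permutations: int = 10,
    variables: Sequence[str] = VARIABLE_NAMES,
) -> pd.DataFrame:
    """Rank input variables by the AUC drop under within-column permutation.

    Each variable is decoupled from its patients by a seeded shuffle across
    the cohort (``n_permutations`` repeats); the drop is the baseline AUC
    minus the mean permuted AUC, and the variable with the largest drop gets
    importance position 1.  Localization is permuted as the (laterality,
    position) pair.
    """
    records = list(records)
    labels = np.asarray([r.is_n0 for r in records], dtype=bool)
    baseline = roc_auc(labels, predict_fn(records))[0]
    fields = {
        "tumor_size": ("tumor_size_mm",),
        "vi": ("vi",),
        "multifocality": ("multifocality",),
        "er": ("er",),
        "histological_type": ("histological_type",),
        "pr": ("pr",),
        "detection_mode": ("detection_mode",),
        "age": ("age_years",),
        "localization": ("laterality", "position"),
        "ki67": ("ki67_percent",),
    }
    rng = np.random.default_rng(seed)
    rows = []
    n = len(records)
    for var in variables:
        attrs = fields[var]
        drops = []
        for _ in range(n_permutations):
            perm = rng.permutation(n)
            shuffled = [
                dataclasses.replace(
                    rec, **{a: getattr(records[perm[i]], a) for a in attrs}
                )
                for i, rec in enumerate(records)
            ]
            drops.append(baseline - roc_auc(labels, predict_fn(shuffled))[0])
        rows.append({"variable": var, "auc_drop": float(np.mean(drops))})
    table = pd.DataFrame(rows).sort_values("auc_drop", ascending=False, kind="stable")
    table["position"] = np.arange(1, len(table) + 1)
    table["baseline_auc"] = baseline
    return table.reset_index(drop=True)
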