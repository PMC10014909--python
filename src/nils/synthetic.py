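"""Synthetic development-cohort generator.

The development data behind the staging tool (800 clinically node-negative
breast cancers, 64.5% pathologically N0) are private, so this module
emulates the cohort's *structure*: the 10 input variables with realistic
marginals, a latent logistic outcome model with configurable effect
directions, and MCAR missingness restricted to the four histopathological
variables (VI, ER, PR, Ki67) that the prediction workflow tolerates.

Default effect directions follow the reported contrasts of the development
cohort: larger tumors, multifocality, vascular invasion and higher Ki67
push toward N+; screening detection pushes toward N0; ER-negative tumors
lean N0.  Magnitudes are fixed so that a default model build reaches a
fused-validation AUC in the mid-0.7 range, the regime the original tool
operates in.  The intercept of the latent model is calibrated by root
finding so the expected N0 fraction matches ``target_n0_prevalence``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Dict, List, Optional

import numpy as np
from scipy.optimize import brentq

from .cohort import PatientRecord
from .exceptions import NilsError

__all__ = [
    "GeneratorConfig",
    "TechnicalValidationSet",
    "generate_cohort",
    "generate_technical_validation_set",
]


def _default_effects() -> Dict[str, float]:
    # per-SD effects for the continuous variables, per-category for the rest
    return {
        "tumor_size": 0.95,
        "vi": 0.95,
        "multifocality": 0.60,
        "er": 0.35,
        "ilc": 0.15,
        "other_type": 0.00,
        "pr": 0.20,
        "screening": -0.60,
        "age": -0.05,
        "ki67": 0.50,
        "central": 0.00,
    }


@dataclass
class GeneratorConfig:
    n: int = 800
    seed: int = 0
    # marginals
    tumor_size_log_mean: float = float(np.log(15.0))  # median 15 mm
    tumor_size_log_sd: float = 0.55
    age_mean: float = 62.0
    age_sd: float = 12.0
    age_min: float = 25.0
    age_max: float = 95.0
    ki67_alpha: float = 1.6  # scaled-beta percent, mean ~31%
    ki67_beta: float = 3.6
    p_screening: float = 0.57
    p_multifocal: float = 0.15
    p_nst: float = 0.80
    p_ilc: float = 0.12
    p_left: float = 0.50
    p_central: float = 0.10
    p_vi: float = 0.25  # marginal VI rate (preserved under the dependence below)
    vi_size_effect: float = 1.2  # per-SD log-odds of VI on tumor size
    vi_ki67_effect: float = 0.8  # per-SD log-odds of VI on Ki67
    p_er_pos: float = 0.85
    p_pr_pos: float = 0.72
    # outcome model
    effects: Dict[str, float] = field(default_factory=_default_effects)
    target_n0_prevalence: float = 0.645
    # MCAR missingness, restricted to the four tolerated variables; the VI
    # rate mirrors the ~30% reporting failure of core needle biopsy
    missing_vi: float = 0.30
    missing_er: float = 0.03
    missing_pr: float = 0.03
    missing_ki67: float = 0.08

    def __post_init__(self) -> None:
        if self.n < 10:
            raise NilsError("cohort size must be >= 10")
        if not (0.0 < self.target_n0_prevalence < 1.0):
            raise NilsError("target_n0_prevalence must be in (0, 1)")
        for name in ("p_screening", "p_multifocal", "p_nst", "p_ilc", "p_left",
                     "p_central", "p_vi", "p_er_pos", "p_pr_pos",
                     "missing_vi", "missing_er", "missing_pr", "missing_ki67"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise NilsError(f"{name} must be in [0, 1]")
        if self.p_nst + self.p_ilc > 1.0:
            raise NilsError("histological type probabilities exceed 1")

    def null(self) -> "GeneratorConfig":
        """A copy with all effects zeroed: labels independent of features."""
        return dataclasses.replace(self, effects={k: 0.0 for k in self.effects})


def _std(x: np.ndarray) -> np.ndarray:
    return (x - x.mean()) / x.std(ddof=1)


def _draw_variables(cfg: GeneratorConfig, rng, n: int) -> dict:
    size = np.exp(rng.normal(cfg.tumor_size_log_mean, cfg.tumor_size_log_sd, n))
    age = rng.normal(cfg.age_mean, cfg.age_sd, n)
    while True:  # truncation by redraw
        bad = (age < cfg.age_min) | (age > cfg.age_max)
        if not bad.any():
            break
        age[bad] = rng.normal(cfg.age_mean, cfg.age_sd, int(bad.sum()))
    ki67 = 100.0 * rng.beta(cfg.ki67_alpha, cfg.ki67_beta, n)
    screening = rng.random(n) < cfg.p_screening
    multifocal = rng.random(n) < cfg.p_multifocal
    u = rng.random(n)
    hist = np.where(u < cfg.p_nst, "NST", np.where(u < cfg.p_nst + cfg.p_ilc, "ILC", "other"))
    left = rng.random(n) < cfg.p_left
    central = rng.random(n) < cfg.p_central
    clock = rng.integers(1, 13, n).astype(float)
    # VI depends on tumor size and Ki67 (mirroring that the imputation
    # sub-models can predict it); the intercept keeps the marginal rate p_vi
    lp_vi = cfg.vi_size_effect * _std(size) + cfg.vi_ki67_effect * _std(ki67)
    b_vi = _calibrated_intercept(lp_vi, 1.0 - cfg.p_vi)
    vi = rng.random(n) < 1.0 / (1.0 + np.exp(-(lp_vi + b_vi)))
    er = rng.random(n) < cfg.p_er_pos
    pr = rng.random(n) < cfg.p_pr_pos
    return dict(size=size, age=age, ki67=ki67, screening=screening,
                multifocal=multifocal, hist=hist, left=left, central=central,
                clock=clock, vi=vi, er=er, pr=pr)


def _linear_predictor(v: dict, eff: Dict[str, float]) -> np.ndarray:
    lp = (
        eff["tumor_size"] * _std(v["size"])
        + eff["vi"] * v["vi"]
        + eff["multifocality"] * v["multifocal"]
        + eff["er"] * v["er"]
        + eff["ilc"] * (v["hist"] == "ILC")
        + eff["other_type"] * (v["hist"] == "other")
        + eff["pr"] * v["pr"]
        + eff["screening"] * v["screening"]
        + eff["age"] * _std(v["age"])
        + eff["ki67"] * _std(v["ki67"])
        + eff["central"] * v["central"]
    )
    return np.asarray(lp, dtype=float)


def _calibrated_intercept(lp: np.ndarray, target_n0: float) -> float:
    target_npos = 1.0 - target_n0
    def f(b):
        return float(np.mean(1.0 / (1.0 + np.exp(-(lp + b)))) - target_npos)
    lo, hi = -30.0, 30.0
    if f(lo) > 0 or f(hi) < 0:
        raise NilsError(
            "intercept calibration failed: attainable N+ prevalence range "
            f"[{f(lo) + target_npos:.4f}, {f(hi) + target_npos:.4f}]"
        )
    return float(brentq(f, lo, hi, xtol=1e-12))


def _assemble_records(
    v: dict, n0: np.ndarray, masks: Optional[dict], prefix: str
) -> List[PatientRecord]:
    records = []
    n = len(n0)
    width = len(str(n))
    for i in range(n):
        central = bool(v["central"][i])
        records.append(
            PatientRecord(
                patient_id=f"{prefix}{i + 1:0{width}d}",
                age_years=float(v["age"][i]),
                detection_mode="screening" if v["screening"][i] else "symptomatic",
                tumor_size_mm=float(v["size"][i]),
                multifocality=bool(v["multifocal"][i]),
                histological_type=str(v["hist"][i]),
                laterality=None if central else ("left" if v["left"][i] else "right"),
                position="central" if central else float(v["clock"][i]),
                vi=None if masks and masks["vi"][i] else bool(v["vi"][i]),
                er=None if masks and masks["er"][i] else bool(v["er"][i]),
                pr=None if masks and masks["pr"][i] else bool(v["pr"][i]),
                ki67_percent=None if masks and masks["ki67"][i] else float(v["ki67"][i]),
                nodal_status="N0" if n0[i] else "N+",
            )
        )
    return records


def generate_cohort(config: GeneratorConfig) -> List[PatientRecord]:
    """Draw a seeded synthetic cohort with nodal-status labels.

    Labels are Bernoulli in the latent logistic model; MCAR missingness is
    applied only to VI/ER/PR/Ki67, after the labels are drawn from the true
    (unmasked) values.
    """
    rng = np.random.default_rng(config.seed)
    v = _draw_variables(config, rng, config.n)
    lp = _linear_predictor(v, config.effects)
    b = _calibrated_intercept(lp, config.target_n0_prevalence)
    p_npos = 1.0 / (1.0 + np.exp(-(lp + b)))
    n0 = rng.random(config.n) >= p_npos
    masks = {
        "vi": rng.random(config.n) < config.missing_vi,
        "er": rng.random(config.n) < config.missing_er,
        "pr": rng.random(config.n) < config.missing_pr,
        "ki67": rng.random(config.n) < config.missing_ki67,
    }
    return _assemble_records(v, n0, masks, prefix="P")


@dataclass
class TechnicalValidationSet:
    """100 reference subjects in four missingness groups of 25."""

    records: List[PatientRecord]
    groups: np.ndarray  # 1..4 per record

    def group_records(self, g: int) -> List[PatientRecord]:
        return [r for r, gg in zip(self.records, self.groups) if gg == g]


def generate_technical_validation_set(
    config: GeneratorConfig,
    seed: int = 0,
    multiple_missing: bool = False,
    inject_ineligible: bool = False,
) -> TechnicalValidationSet:
    """Draw the 100-subject interface-validation set.

    Groups of 25: (1) complete; (2) VI missing; (3) one of ER/PR/Ki67
    missing, VI present; (4) VI missing plus one of ER/PR/Ki67 missing.  By
    default exactly one receptor variable is masked in groups 3-4
    (``multiple_missing`` masks each with probability 1/2, at least one).
    ``inject_ineligible`` blanks multifocality on two subjects (one each in
    groups 1 and 2) to replicate a 98-evaluable concordance scenario.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(7,)))
    v = _draw_variables(config, rng, 100)
    lp = _linear_predictor(v, config.effects)
    b = _calibrated_intercept(lp, config.target_n0_prevalence)
    n0 = rng.random(100) >= 1.0 / (1.0 + np.exp(-(lp + b)))
    records = _assemble_records(v, n0, masks=None, prefix="T")
    groups = np.repeat([1, 2, 3, 4], 25)

    def mask_receptor(rec: PatientRecord) -> PatientRecord:
        names = ("er", "pr", "ki67_percent")
        if multiple_missing:
            which = [n for n in names if rng.random() < 0.5]
            if not which:
                which = [names[rng.integers(3)]]
        else:
            which = [names[rng.integers(3)]]
        return dataclasses.replace(rec, **{n: None for n in which})

    out = []
    for rec, g in zip(records, groups):
        if g in (2, 4):
            rec = dataclasses.replace(rec, vi=None)
        if g in (3, 4):
            rec = mask_receptor(rec)
        out.append(rec)
    if inject_ineligible:
        for idx in (0, 25):
            out[idx] = dataclasses.replace(out[idx], multifocality=None)
    return TechnicalValidationSet(records=out, groups=groups)
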