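import numpy as np
import pytest
from hypothesis import settings

from nils.cohort import PatientRecord
from nils.synthetic import GeneratorConfig, generate_cohort
from nils.workflow import BuildConfig, build_registry

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


def make_record(**overrides) -> PatientRecord:
    """A complete, prediction-eligible record with sensible defaults."""
    kwargs = dict(
        patient_id="X1",
        age_years=61.0,
        detection_mode="screening",
        tumor_size_mm=14.0,
        multifocality=False,
        histological_type="NST",
        laterality="right",
        position=10.5,
        vi=False,
        er=True,
        pr=True,
        ki67_percent=22.0,
        nodal_status="N0",
    )
    kwargs.update(overrides)
    return PatientRecord(**kwargs)


@pytest.fixture(scope="session")
def complete_cohort():
    """80 fully observed records (no missingness) with labels."""
    cfg = GeneratorConfig(
        n=80, seed=11, missing_vi=0.0, missing_er=0.0, missing_pr=0.0, missing_ki67=0.0
    )
    return generate_cohort(cfg)


@pytest.fixture(scope="session")
def small_cohort():
    """160 records with the default missingness pattern."""
    return generate_cohort(GeneratorConfig(n=160, seed=3))


TINY_BUILD = BuildConfig(
    seed=5,
    lambda_grid=(0.01,),
    ensemble_repeats=2,
    cv_ensemble_repeats=1,
    cv_repeats=2,
    max_iterations=200,
)


@pytest.fixture(scope="session")
def tiny_build(small_cohort):
    """A small but complete registry build (all four models, cut-points,
    backgrounds) used by workflow-level tests."""
    return build_registry(small_cohort, TINY_BUILD)


# ---------------------------------------------------------------------------
# independent brute-force oracles shared across test modules
# ---------------------------------------------------------------------------

def auc_pairwise_oracle(is_n0, scores) -> float:
    """Double-loop Mann-Whitney AUC, ties counted 1/2."""
    is_n0 = np.asarray(is_n0, dtype=bool)
    scores = np.asarray(scores, dtype=float)
    pos = scores[is_n0]
    neg = scores[~is_n0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def cutoff_oracle(is_n0, probs, max_fnr):
    """Exhaustive search over candidate thresholds with plain loops."""
    is_n0 = np.asarray(is_n0, dtype=bool)
    probs = np.asarray(probs, dtype=float)
    u = sorted(set(probs))
    candidates = [u[0] / 2.0]
    candidates += [(a + b) / 2.0 for a, b in zip(u[:-1], u[1:])]
    candidates += [(u[-1] + 1.0) / 2.0]
    best = None
    for c in candidates:
        tp = tn = fp = fn = 0
        for y, p in zip(is_n0, probs):
            pred_n0 = p >= c
            if y and pred_n0:
                tn += 1
            elif y:
                fp += 1
            elif pred_n0:
                fn += 1
            else:
                tp += 1
        fnr = fn / (fn + tp)
        if fnr > max_fnr:
            continue
        reduction = (tn + fn) / len(probs)
        if best is None or reduction > best[1] or (reduction == best[1] and c > best[0]):
            best = (c, reduction)
    return best
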