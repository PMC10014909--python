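"""Independent reference recomputation of the prediction path.

This module re-derives a patient's prediction directly from a serialized
registry dictionary using plain Python arithmetic (no numpy, none of the
package's encoding or forward-pass code).  It exists so the concordance
harness compares two genuinely separate implementations over the same
parameters, the way the deployed interface was checked against the original
algorithm.  Keep this file free of imports from the rest of the package.
"""

from __future__ import annotations

import math
from typing import Tuple

_CLIP = 1e-12


def _sigmoid(z: float) -> float:
    if z >= 0:
        p = 1.0 / (1.0 + math.exp(-z))
    else:
        ez = math.exp(z)
        p = ez / (1.0 + ez)
    return min(max(p, _CLIP), 1.0 - _CLIP)


def _quadrant(laterality, position) -> str:
    if position == "central":
        return "central"
    hp = float(position) % 12.0
    sector = int(hp // 3)
    table = {
        "right": ("UIQ", "LIQ", "LOQ", "UOQ"),
        "left": ("UOQ", "LOQ", "LIQ", "UIQ"),
    }
    return table[laterality][sector]


def _encode(record, norm: dict, variant: str, vi_value=None) -> list:
    full = variant in ("n0_full", "vi_full")
    uses_vi = variant in ("n0_full", "n0_reduced")
    x = []
    ts = norm["tumor_size_mm"]
    x.append((record.tumor_size_mm - ts["mean"]) / ts["sd"])
    if uses_vi:
        x.append(float(vi_value) if vi_value is not None else (1.0 if record.vi else 0.0))
    x.append(1.0 if record.multifocality else 0.0)
    if full:
        x.append(1.0 if record.er else 0.0)
    x.extend({"NST": [1.0, 0.0, 0.0], "ILC": [0.0, 1.0, 0.0], "other": [0.0, 0.0, 1.0]}[
        record.histological_type
    ])
    if full:
        x.append(1.0 if record.pr else 0.0)
    x.append(1.0 if record.detection_mode == "screening" else 0.0)
    ag = norm["age_years"]
    x.append((record.age_years - ag["mean"]) / ag["sd"])
    q = _quadrant(record.laterality, record.position)
    x.extend(1.0 if q == name else 0.0 for name in ("central", "UIQ", "UOQ", "LIQ", "LOQ"))
    if full:
        ki = norm["ki67_percent"]
        x.append((record.ki67_percent - ki["mean"]) / ki["sd"])
    return x


def _forward(member: dict, x: list) -> float:
    z = member["b2"]
    for w_row, b, w_out in zip(member["w1"], member["b1"], member["w2"]):
        s = b
        for w, xi in zip(w_row, x):
            s += w * xi
        z += w_out * math.tanh(s)
    return _sigmoid(z)


def _ensemble(model: dict, x: list) -> float:
    total = 0.0
    for member in model["members"]:
        total += _forward(member, x)
    return total / len(model["members"])


def reference_predict(registry: dict, record) -> Tuple[float, float, str]:
    """Recompute (p_n0, cut-point, pathway) for one eligible record.

    ``registry`` is the JSON dictionary of a serialized model registry;
    ``record`` any object exposing the patient-record attributes.
    """
    if record.multifocality is None:
        raise ValueError("ineligible record: multifocality missing")
    norm = registry["normalization"]
    receptors = (
        record.er is not None
        and record.pr is not None
        and record.ki67_percent is not None
    )
    vi_value = None
    if record.vi is None:
        imputer = "vi_full" if receptors else "vi_reduced"
        p_vi = _ensemble(registry["models"][imputer], _encode(record, norm, imputer))
        threshold = registry.get("vi_hard_threshold")
        vi_value = p_vi if threshold is None else (1.0 if p_vi >= threshold else 0.0)
        pathway = "full_vi_imputed" if receptors else "reduced_vi_imputed"
    else:
        pathway = "full" if receptors else "reduced"
    n0_model = "n0_full" if receptors else "n0_reduced"
    p = _ensemble(
        registry["models"][n0_model], _encode(record, norm, n0_model, vi_value=vi_value)
    )
    cut = registry["cutpoints"]["full" if receptors else "reduced"]
    return p, cut, pathway
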