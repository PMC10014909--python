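"""Smoothed background distribution of predicted probabilities.

The risk display contextualizes a patient's estimate against the
distribution of predicted probabilities in the development population.  The
empirical probabilities are mapped to logits z = ln(p/(1-p)), smoothed with
a Gaussian kernel of fixed (absolute) bandwidth on the logit scale, and
mapped back to the probability scale with the change-of-variables factor
1/(p(1-p)).  The logit transform keeps the support strictly inside (0, 1)
and the Jacobian makes the returned density integrate to one there.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import NilsError

__all__ = ["SmoothedDistribution", "smooth_probabilities"]

_SQRT_2PI = np.sqrt(2.0 * np.pi)


@dataclass
class SmoothedDistribution:
    """A density over p in (0, 1) evaluated on a logit-uniform grid."""

    grid: np.ndarray  # probabilities, strictly increasing inside (0, 1)
    density: np.ndarray  # per-unit-p density at grid points
    bandwidth: float  # Gaussian kernel bandwidth, logit-scale units
    n_source: int
    model_key: str = ""
    logit_grid: np.ndarray = field(default=None, repr=False)
    logit_density: np.ndarray = field(default=None, repr=False)

    def to_dict(self) -> dict:
        return {
            "grid": np.asarray(self.grid).tolist(),
            "density": np.asarray(self.density).tolist(),
            "bandwidth": self.bandwidth,
            "n_source": self.n_source,
            "model_key": self.model_key,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SmoothedDistribution":
        return cls(
            grid=np.asarray(d["grid"], dtype=float),
            density=np.asarray(d["density"], dtype=float),
            bandwidth=float(d["bandwidth"]),
            n_source=int(d["n_source"]),
            model_key=d.get("model_key", ""),
        )

    def integral(self) -> float:
        return float(np.trapezoid(self.density, self.grid))


def smooth_probabilities(
    probs, bandwidth: float = 0.5, grid_size: int = 512, model_key: str = ""
) -> SmoothedDistribution:
    """Gaussian KDE of probabilities on the logit scale.

    The grid is uniform in logit over [min(z) - 4 bw, max(z) + 4 bw] (z the
    logits of the inputs) and mapped back to p; the returned density is on
    the p scale, Jacobian applied, and integrates to 1 within ~1%.
    """
    p = np.asarray(probs, dtype=float)
    if p.size == 0:
        raise NilsError("cannot smooth an empty set of probabilities")
    if np.any(p <= 0.0) or np.any(p >= 1.0):
        raise NilsError("probabilities must be strictly inside (0, 1)")
    if bandwidth <= 0:
        raise NilsError("bandwidth must be > 0")
    z = np.log(p / (1.0 - p))
    zg = np.linspace(z.min() - 4.0 * bandwidth, z.max() + 4.0 * bandwidth, grid_size)
    # fixed-bandwidth Gaussian KDE on the logit scale
    diff = (zg[:, None] - z[None, :]) / bandwidth
    fz = np.exp(-0.5 * diff * diff).sum(axis=1) / (p.size * bandwidth * _SQRT_2PI)
    pg = 1.0 / (1.0 + np.exp(-zg))
    fp = fz / (pg * (1.0 - pg))
    return SmoothedDistribution(
        grid=pg,
        density=fp,
        bandwidth=float(bandwidth),
        n_source=int(p.size),
        model_key=model_key,
        logit_grid=zg,
        logit_density=fz,
    )
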