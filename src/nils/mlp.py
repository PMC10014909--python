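"""Single multilayer perceptron: forward pass and weight-decay training.

Each network has one hidden layer of ``tanh`` units (default 10) and a single
logistic output encoding a probability.  Training minimizes

    L(W) = mean binary cross-entropy + lambda_decay * sum(weights**2)

with biases excluded from the penalty, by full-batch L-BFGS with analytic
gradients.  Mean (rather than summed) cross-entropy gives ``lambda_decay`` a
scale independent of the training-set size, so one decay grid is usable
across member-subset sizes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.optimize import minimize

from .exceptions import TrainingError

__all__ = ["MLPParameters", "TrainingConfig", "mlp_forward", "train_mlp"]

_P_EPS = 1e-12  # forward-pass outputs are clipped strictly inside (0, 1)


@dataclass
class TrainingConfig:
    lambda_decay: float = 0.01
    max_iterations: int = 500
    convergence_tolerance: float = 1e-8
    init_scale: float = 0.5
    hidden_dim: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.max_iterations <= 0:
            raise TrainingError("max_iterations must be > 0")
        if self.convergence_tolerance <= 0:
            raise TrainingError("convergence_tolerance must be > 0")
        if self.lambda_decay < 0:
            raise TrainingError("lambda_decay must be nonnegative")


@dataclass
class MLPParameters:
    """Weights of one trained network.

    ``w1`` is (hidden, input), ``b1`` (hidden,), ``w2`` (hidden,), ``b2``
    scalar.  ``loss_trace`` records the penalized loss at each accepted
    optimizer iterate (diagnostic only; not serialized).
    """

    input_dim: int
    hidden_dim: int
    w1: np.ndarray
    b1: np.ndarray
    w2: np.ndarray
    b2: float
    lambda_decay: float = 0.0
    loss_trace: Optional[np.ndarray] = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        self.w1 = np.asarray(self.w1, dtype=float)
        self.b1 = np.asarray(self.b1, dtype=float)
        self.w2 = np.asarray(self.w2, dtype=float)
        if self.w1.shape != (self.hidden_dim, self.input_dim):
            raise TrainingError(f"w1 shape {self.w1.shape} inconsistent")
        if self.b1.shape != (self.hidden_dim,) or self.w2.shape != (self.hidden_dim,):
            raise TrainingError("bias/output weight shapes inconsistent")
        if not (
            np.all(np.isfinite(self.w1))
            and np.all(np.isfinite(self.b1))
            and np.all(np.isfinite(self.w2))
            and np.isfinite(self.b2)
        ):
            raise TrainingError("non-finite parameters")

    def to_dict(self) -> dict:
        return {
            "input_dim": self.input_dim,
            "hidden_dim": self.hidden_dim,
            "w1": self.w1.tolist(),
            "b1": self.b1.tolist(),
            "w2": self.w2.tolist(),
            "b2": self.b2,
            "lambda_decay": self.lambda_decay,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MLPParameters":
        return cls(
            input_dim=d["input_dim"],
            hidden_dim=d["hidden_dim"],
            w1=np.asarray(d["w1"], dtype=float),
            b1=np.asarray(d["b1"], dtype=float),
            w2=np.asarray(d["w2"], dtype=float),
            b2=float(d["b2"]),
            lambda_decay=float(d.get("lambda_decay", 0.0)),
        )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    # numerically stable logistic
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _logits(params: MLPParameters, x: np.ndarray) -> np.ndarray:
    a = np.tanh(x @ params.w1.T + params.b1)
    return a @ params.w2 + params.b2


def mlp_forward(params: MLPParameters, x) -> np.ndarray:
    """Network output probability, strictly inside (0, 1).

    ``x`` may be one vector of length ``input_dim`` or a 2-D batch; the
    return is a scalar or a 1-D array correspondingly.
    """
    x = np.asarray(x, dtype=float)
    single = x.ndim == 1
    if single:
        x = x[None, :]
    if x.shape[1] != params.input_dim:
        raise TrainingError(
            f"input has {x.shape[1]} features, network expects {params.input_dim}"
        )
    p = np.clip(_sigmoid(_logits(params, x)), _P_EPS, 1.0 - _P_EPS)
    return float(p[0]) if single else p


def _pack(w1, b1, w2, b2):
    return np.concatenate([w1.ravel(), b1, w2, [b2]])


def _unpack(theta, d, h):
    w1 = theta[: h * d].reshape(h, d)
    b1 = theta[h * d : h * d + h]
    w2 = theta[h * d + h : h * d + 2 * h]
    b2 = theta[-1]
    return w1, b1, w2, b2


def _loss_grad(theta, X, y, lam, d, h):
    w1, b1, w2, b2 = _unpack(theta, d, h)
    n = X.shape[0]
    a = np.tanh(X @ w1.T + b1)  # (n, h)
    z = a @ w2 + b2
    # mean BCE via the softplus identity: log(1+e^z) - y z, stable for large |z|
    bce = float(np.mean(np.logaddexp(0.0, z) - y * z))
    loss = bce + lam * (np.sum(w1 * w1) + np.sum(w2 * w2))
    delta = (_sigmoid(z) - y) / n  # dL/dz
    g_w2 = a.T @ delta + 2.0 * lam * w2
    g_b2 = float(np.sum(delta))
    g_pre = (np.outer(delta, w2)) * (1.0 - a * a)  # (n, h)
    g_w1 = g_pre.T @ X + 2.0 * lam * w1
    g_b1 = g_pre.sum(axis=0)
    return loss, _pack(g_w1, g_b1, g_w2, g_b2)


def train_mlp(X, y, config: TrainingConfig) -> MLPParameters:
    """Train one MLP on encoded inputs ``X`` (n, d) with 0/1 labels ``y``.

    Deterministic given ``config.seed``: weights start uniform in
    (-init_scale, +init_scale) from a seeded generator, biases at zero, and
    optimization is full-batch L-BFGS.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or X.shape[0] != y.shape[0]:
        raise TrainingError("X must be (n, d) with one label per row")
    if not (np.any(y == 0) and np.any(y == 1)):
        raise TrainingError("training set must contain both classes")
    n, d = X.shape
    h = config.hidden_dim
    rng = np.random.default_rng(config.seed)
    w1 = rng.uniform(-config.init_scale, config.init_scale, size=(h, d))
    w2 = rng.uniform(-config.init_scale, config.init_scale, size=h)
    theta0 = _pack(w1, np.zeros(h), w2, 0.0)

    trace = [ _loss_grad(theta0, X, y, config.lambda_decay, d, h)[0] ]

    def cb(theta):
        trace.append(_loss_grad(theta, X, y, config.lambda_decay, d, h)[0])

    res = minimize(
        _loss_grad,
        theta0,
        args=(X, y, config.lambda_decay, d, h),
        method="L-BFGS-B",
        jac=True,
        callback=cb,
        options={
            "maxiter": config.max_iterations,
            "ftol": config.convergence_tolerance,
            "gtol": 1e-7,
        },
    )
    if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
        raise TrainingError(
            f"non-finite training loss (lambda={config.lambda_decay}, n={n}, d={d})"
        )
    w1, b1, w2, b2 = _unpack(res.x, d, h)
    return MLPParameters(
        input_dim=d,
        hidden_dim=h,
        w1=w1,
        b1=b1,
        w2=w2,
        b2=float(b2),
        lambda_decay=config.lambda_decay,
        loss_trace=np.asarray(trace),
    )
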