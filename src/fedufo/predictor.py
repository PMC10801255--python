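"""One-hidden-layer softmax classifier with a per-sample-weighted loss.

The backbone every trainer in this package shares: a fully connected
hidden layer (ReLU) followed by a softmax output.  Implemented directly
in NumPy with analytic gradients — the architecture is small enough that
an autodiff framework would add dependency weight without adding
capability, and the weighted-gradient contract (zero-weight samples
contribute nothing, weights multiply per-sample gradients) is exactly
what the fair trainers rely on.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

PARAM_KEYS = ("W1", "b1", "W2", "b2")


@dataclass
class PredictorState:
    """Parameters of the classifier plus optimizer accumulators."""

    params: dict[str, np.ndarray]
    hidden_width: int
    step_count: int = 0
    opt_m: dict[str, np.ndarray] = field(default_factory=dict)
    opt_v: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_classes(self) -> int:
        return self.params["b2"].shape[0]

    @property
    def n_features(self) -> int:
        return self.params["W1"].shape[0]

    def copy(self) -> "PredictorState":
        return PredictorState(
            params={k: v.copy() for k, v in self.params.items()},
            hidden_width=self.hidden_width,
            step_count=self.step_count,
            opt_m={k: v.copy() for k, v in self.opt_m.items()},
            opt_v={k: v.copy() for k, v in self.opt_v.items()},
        )

    def check_finite(self) -> None:
        for k, v in self.params.items():
            if not np.isfinite(v).all():
                raise FloatingPointError(f"parameter {k} became non-finite")

    def to_json(self) -> str:
        return json.dumps(
            {
                "hidden_width": self.hidden_width,
                "step_count": self.step_count,
                "params": {k: v.tolist() for k, v in self.params.items()},
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "PredictorState":
        obj = json.loads(text)
        return cls(
            params={k: np.asarray(v, float) for k, v in obj["params"].items()},
            hidden_width=obj["hidden_width"],
            step_count=obj["step_count"],
        )


def init_predictor(d: int, hidden_width: int, K: int, seed: int) -> PredictorState:
    """Fresh parameters: weights ~ Normal(0, 1/fan_in), biases zero.

    ``hidden_width`` defaults to 64 throughout the package (256 is the
    conventional choice for much larger tables).  Deterministic given seed.
    """
    if min(d, hidden_width, K) < 1:
        raise ValueError("d, hidden_width, K must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0x1217A7]))
    params = {
        "W1": rng.standard_normal((d, hidden_width)) / np.sqrt(d),
        "b1": np.zeros(hidden_width),
        "W2": rng.standard_normal((hidden_width, K)) / np.sqrt(hidden_width),
        "b2": np.zeros(K),
    }
    return PredictorState(params=params, hidden_width=hidden_width)


def _forward(params: dict[str, np.ndarray], X: np.ndarray):
    pre = X @ params["W1"] + params["b1"]
    hid = np.maximum(pre, 0.0)
    logits = hid @ params["W2"] + params["b2"]
    return pre, hid, logits


def predict_logits(state: PredictorState, X: np.ndarray) -> np.ndarray:
    return _forward(state.params, np.atleast_2d(X))[2]


def predict_proba(state: PredictorState, X: np.ndarray) -> np.ndarray:
    logits = predict_logits(state, X)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def predict(state: PredictorState, X: np.ndarray) -> np.ndarray:
    return predict_logits(state, X).argmax(axis=1)


def cross_entropy(state: PredictorState, X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Per-sample cross-entropy, computed from logits (log-sum-exp stable)."""
    logits = predict_logits(state, X)
    z = logits - logits.max(axis=1, keepdims=True)
    lse = np.log(np.exp(z).sum(axis=1))
    return lse - z[np.arange(len(y)), y]


def weighted_loss_grad(
    state: PredictorState,
    X: np.ndarray,
    y: np.ndarray,
    sample_weights: np.ndarray,
) -> tuple[float, dict[str, np.ndarray]]:
    """Weighted mean cross-entropy and its exact gradient.

    loss = sum_j w_j * CE(softmax(f(x_j)), y_j) / |batch|; a zero-weight
    sample contributes nothing to either the loss or the gradient.
    """
    X = np.atleast_2d(X)
    y = np.asarray(y, int)
    w = np.asarray(sample_weights, float)
    if len(X) == 0:
        raise ValueError("empty batch")
    if len(w) != len(X) or len(y) != len(X):
        raise ValueError("batch, labels and weights must have equal length")
    if not np.isfinite(w).all() or (w < 0).any():
        raise ValueError("sample weights must be finite and non-negative")
    params = state.params
    B = len(X)
    pre, hid, logits = _forward(params, X)
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    proba = e / e.sum(axis=1, keepdims=True)
    lse = np.log(e.sum(axis=1))
    ce = lse - z[np.arange(B), y]
    loss = float(np.dot(w, ce) / B)
    # d loss / d logits
    dlogits = proba.copy()
    dlogits[np.arange(B), y] -= 1.0
    dlogits *= (w / B)[:, None]
    dhid = dlogits @ params["W2"].T
    dpre = dhid * (pre > 0)
    grad = {
        "W2": hid.T @ dlogits,
        "b2": dlogits.sum(axis=0),
        "W1": X.T @ dpre,
        "b1": dpre.sum(axis=0),
    }
    return loss, grad


def apply_update(
    state: PredictorState,
    grad: dict[str, np.ndarray],
    eta: float,
    optimizer: str = "sgd",
    betas: tuple[float, float] = (0.9, 0.999),
    eps: float = 1e-8,
) -> PredictorState:
    """One optimizer step; returns a new state, input untouched.

    ``sgd`` is the literal descent rule the fairness algebra assumes
    (weighted gradients scale the step exactly); ``adam`` is the
    practical default for experiments.
    """
    if eta < 0:
        raise ValueError("eta must be >= 0")
    for k in PARAM_KEYS:
        if grad[k].shape != state.params[k].shape:
            raise ValueError(f"gradient shape mismatch for {k}")
        if not np.isfinite(grad[k]).all():
            raise FloatingPointError(f"non-finite gradient for {k}")
    new = state.copy()
    new.step_count = state.step_count + 1
    if optimizer == "sgd":
        for k in PARAM_KEYS:
            new.params[k] = state.params[k] - eta * grad[k]
    elif optimizer == "adam":
        b1, b2 = betas
        t = new.step_count
        if not new.opt_m:
            new.opt_m = {k: np.zeros_like(v) for k, v in state.params.items()}
            new.opt_v = {k: np.zeros_like(v) for k, v in state.params.items()}
        for k in PARAM_KEYS:
            new.opt_m[k] = b1 * new.opt_m[k] + (1 - b1) * grad[k]
            new.opt_v[k] = b2 * new.opt_v[k] + (1 - b2) * grad[k] ** 2
            mhat = new.opt_m[k] / (1 - b1**t)
            vhat = new.opt_v[k] / (1 - b2**t)
            new.params[k] = state.params[k] - eta * mhat / (np.sqrt(vhat) + eps)
    else:
        raise ValueError(f"unknown optimizer {optimizer!r}")
    new.check_finite()
    return new
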