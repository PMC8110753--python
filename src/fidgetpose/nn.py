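"""Minimal dense neural-network core: forward/backward passes and Adam.

Implements exactly the ingredients the shallow classifier needs — dense
layers, a ReLU first hidden layer, parametric-ReLU later hidden layers
(one learned slope per layer, initialized at 0.25), inverted dropout
between hidden layers, a single sigmoid output unit, binary
cross-entropy loss, and the Adam optimizer with bias-corrected first and
second moment estimates.  Everything is plain numpy and fully seeded.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit


def sigmoid(z: np.ndarray) -> np.ndarray:
    return expit(z)


def bce_from_logits(logits: np.ndarray, y: np.ndarray) -> float:
    """Mean binary cross-entropy, computed stably from pre-sigmoid logits."""
    return float(np.mean(np.logaddexp(0.0, logits) - y * logits))


class ShallowMLP:
    """A dense network ``input -> hidden_1 (ReLU) -> [dropout -> hidden_l
    (PReLU)]* -> 1 (sigmoid)``.

    Parameters are He-initialized from a seeded generator.  Dropout (if
    ``dropout_rate > 0`` and the net has >= 2 hidden layers) acts between
    hidden layers during training passes only.
    """

    def __init__(self, input_dim: int, hidden_sizes, dropout_rate: float = 0.0,
                 prelu_init: float = 0.25, rng: np.random.Generator | int | None = None):
        if not hidden_sizes:
            raise ValueError("at least one hidden layer is required")
        rng = np.random.default_rng(rng)
        self.input_dim = int(input_dim)
        self.hidden_sizes = list(hidden_sizes)
        self.dropout_rate = float(dropout_rate) if len(self.hidden_sizes) >= 2 else 0.0
        sizes = [self.input_dim] + self.hidden_sizes + [1]
        self.params: dict[str, np.ndarray] = {}
        for l in range(len(sizes) - 1):
            fan_in = sizes[l]
            self.params[f"W{l}"] = rng.normal(0.0, np.sqrt(2.0 / fan_in), (sizes[l], sizes[l + 1]))
            self.params[f"b{l}"] = np.zeros(sizes[l + 1])
        for l in range(1, len(self.hidden_sizes)):
            self.params[f"a{l}"] = np.array(float(prelu_init))  # PReLU slope per layer

    @property
    def n_hidden(self) -> int:
        return len(self.hidden_sizes)

    def forward(self, X: np.ndarray, train: bool = False,
                rng: np.random.Generator | None = None):
        """Return (logits, cache).  Dropout masks are drawn only when
        ``train`` is true; inference is deterministic."""
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != self.input_dim:
            raise ValueError(f"expected input of shape (n, {self.input_dim}), got {X.shape}")
        cache = {"X": X, "z": [], "a": [], "mask": []}
        h = X
        for l in range(self.n_hidden):
            if l > 0 and self.dropout_rate > 0 and train:
                mask = (rng.random(h.shape) >= self.dropout_rate) / (1.0 - self.dropout_rate)
                h = h * mask
            else:
                mask = None
            cache["mask"].append(mask)
            z = h @ self.params[f"W{l}"] + self.params[f"b{l}"]
            if l == 0:
                a = np.maximum(z, 0.0)
            else:
                slope = self.params[f"a{l}"]
                a = np.where(z > 0, z, slope * z)
            cache["z"].append(z)
            cache["a"].append(a)
            h = a
        L = self.n_hidden
        logits = (h @ self.params[f"W{L}"] + self.params[f"b{L}"]).ravel()
        cache["h_out"] = h
        return logits, cache

    def backward(self, cache, logits: np.ndarray, y: np.ndarray):
        """Gradients of mean BCE w.r.t. every parameter."""
        m = len(y)
        grads: dict[str, np.ndarray] = {}
        L = self.n_hidden
        dz_out = ((sigmoid(logits) - y) / m)[:, None]
        grads[f"W{L}"] = cache["h_out"].T @ dz_out
        grads[f"b{L}"] = dz_out.sum(axis=0)
        da = dz_out @ self.params[f"W{L}"].T
        for l in range(L - 1, -1, -1):
            z = cache["z"][l]
            if l == 0:
                dz = da * (z > 0)
            else:
                slope = self.params[f"a{l}"]
                dz = da * np.where(z > 0, 1.0, slope)
                grads[f"a{l}"] = np.array((da * np.where(z > 0, 0.0, z)).sum())
            h_in = cache["X"] if l == 0 else cache["a"][l - 1]
            if cache["mask"][l] is not None:
                h_in = h_in * cache["mask"][l]
            grads[f"W{l}"] = h_in.T @ dz
            grads[f"b{l}"] = dz.sum(axis=0)
            if l > 0:
                da = dz @ self.params[f"W{l}"].T
                if cache["mask"][l] is not None:
                    da = da * cache["mask"][l]
        return grads

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """Sigmoid outputs, clipped to the open interval (0, 1)."""
        logits, _ = self.forward(X, train=False)
        return np.clip(sigmoid(logits), 1e-12, 1.0 - 1e-12)

    def copy_params(self) -> dict[str, np.ndarray]:
        return {k: v.copy() for k, v in self.params.items()}

    def set_params(self, params: dict[str, np.ndarray]) -> None:
        self.params = {k: np.array(v, dtype=float) for k, v in params.items()}


class Adam:
    """Adam optimizer with bias-corrected first/second moment estimates."""

    def __init__(self, params: dict[str, np.ndarray], learning_rate: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.lr = learning_rate
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, params: dict[str, np.ndarray], grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            m_hat = self.m[k] / (1 - self.beta1 ** self.t)
            v_hat = self.v[k] / (1 - self.beta2 ** self.t)
            params[k] = params[k] - self.lr * m_hat / (np.sqrt(v_hat) + self.eps)
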