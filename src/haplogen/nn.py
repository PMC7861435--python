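"""Minimal dense-network machinery: layers, activations, Adam, backprop.

Implements exactly what the adversarial model needs — fully connected
layers with LeakyReLU / tanh / sigmoid / identity activations, binary
cross-entropy with its gradient, L2 weight decay, and the Adam optimizer —
on plain numpy arrays.  Weights use Glorot-uniform initialization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["DenseNet", "Adam", "bce_loss", "bce_grad"]

_EPS = 1e-7


def _activate(z: np.ndarray, kind: str, alpha: float) -> np.ndarray:
    if kind == "leaky_relu":
        return np.where(z > 0, z, alpha * z)
    if kind == "tanh":
        return np.tanh(z)
    if kind == "sigmoid":
        return 1.0 / (1.0 + np.exp(-z))
    if kind == "linear":
        return z
    raise ValueError(f"unknown activation {kind!r}")


def _activate_grad(z: np.ndarray, a: np.ndarray, kind: str, alpha: float) -> np.ndarray:
    if kind == "leaky_relu":
        return np.where(z > 0, 1.0, alpha)
    if kind == "tanh":
        return 1.0 - a * a
    if kind == "sigmoid":
        return a * (1.0 - a)
    if kind == "linear":
        return np.ones_like(z)
    raise ValueError(f"unknown activation {kind!r}")


def bce_loss(y_pred: np.ndarray, y_true: np.ndarray) -> float:
    """Mean binary cross-entropy."""
    p = np.clip(y_pred, _EPS, 1.0 - _EPS)
    return float(-np.mean(y_true * np.log(p) + (1.0 - y_true) * np.log(1.0 - p)))


def bce_grad(y_pred: np.ndarray, y_true: np.ndarray) -> np.ndarray:
    """d(mean BCE)/d(y_pred)."""
    p = np.clip(y_pred, _EPS, 1.0 - _EPS)
    return (p - y_true) / (p * (1.0 - p)) / y_true.size


@dataclass
class DenseNet:
    """A stack of dense layers with per-layer activations.

    ``sizes`` lists layer widths input-first; ``activations`` has one entry
    per weight layer.  ``l2`` is the weight-decay coefficient added to the
    weight (not bias) gradients.
    """

    sizes: tuple[int, ...]
    activations: tuple[str, ...]
    leaky_alpha: float = 0.01
    l2: float = 0.0
    l2_layers: tuple[int, ...] | None = None  # None = every weight layer
    weights: list[np.ndarray] = field(default_factory=list, repr=False)
    biases: list[np.ndarray] = field(default_factory=list, repr=False)

    def __post_init__(self) -> None:
        if len(self.activations) != len(self.sizes) - 1:
            raise ValueError("need one activation per weight layer")

    def init_params(self, rng: np.random.Generator) -> None:
        self.weights, self.biases = [], []
        for fan_in, fan_out in zip(self.sizes[:-1], self.sizes[1:]):
            limit = np.sqrt(6.0 / (fan_in + fan_out))
            self.weights.append(rng.uniform(-limit, limit, size=(fan_in, fan_out)))
            self.biases.append(np.zeros(fan_out))

    @property
    def params(self) -> list[np.ndarray]:
        return self.weights + self.biases

    def forward(self, x: np.ndarray, cache: bool = False):
        """Forward pass; with ``cache`` returns the per-layer (z, a) pairs."""
        a = x
        zs, acts = [], [x]
        for W, b, kind in zip(self.weights, self.biases, self.activations):
            z = a @ W + b
            a = _activate(z, kind, self.leaky_alpha)
            if cache:
                zs.append(z)
                acts.append(a)
        return (a, zs, acts) if cache else a

    def backward(
        self, zs: list[np.ndarray], acts: list[np.ndarray], grad_out: np.ndarray
    ):
        """Backprop ``grad_out`` (dL/d output activation).

        Returns ``(param_grads, grad_input)`` with param_grads ordered as
        ``self.params``.
        """
        gW = [None] * len(self.weights)
        gb = [None] * len(self.biases)
        delta = grad_out
        for layer in range(len(self.weights) - 1, -1, -1):
            delta = delta * _activate_grad(
                zs[layer], acts[layer + 1], self.activations[layer], self.leaky_alpha
            )
            gW[layer] = acts[layer].T @ delta
            if self.l2 and (self.l2_layers is None or layer in self.l2_layers):
                gW[layer] = gW[layer] + self.l2 * self.weights[layer]
            gb[layer] = delta.sum(axis=0)
            delta = delta @ self.weights[layer].T
        return gW + gb, delta


class Adam:
    """Adam optimizer over a list of parameter arrays (updated in place)."""

    def __init__(
        self,
        params: list[np.ndarray],
        lr: float,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
    ):
        self.params = params
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1.0 - self.beta1) * g
            v *= self.beta2
            v += (1.0 - self.beta2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
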