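"""Dense feed-forward building blocks with hand-derived backpropagation.

The estimators in this package need gradients that flow through weights
*generated* by another network, so the primitives here expose explicit
forward passes (with caches) and matching backward passes that composite
models can chain.  Everything is float64 numpy; batches are row-major.
"""
from __future__ import annotations

from typing import Callable

import numpy as np

__all__ = ["ACTIVATIONS", "DenseMLP", "Adam", "get_activation"]


def _elu(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0, u, np.expm1(np.minimum(u, 0.0)))


def _elu_grad(u: np.ndarray) -> np.ndarray:
    return np.where(u > 0, 1.0, np.exp(np.minimum(u, 0.0)))


def _tanh_grad(u: np.ndarray) -> np.ndarray:
    t = np.tanh(u)
    return 1.0 - t * t


#: name -> (value, derivative w.r.t. pre-activation).  All smooth, zero at zero.
ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "elu": (_elu, _elu_grad),
    "tanh": (np.tanh, _tanh_grad),
    "softplus": (lambda u: np.logaddexp(0.0, u), lambda u: 1.0 / (1.0 + np.exp(-u))),
}


def get_activation(name: str) -> tuple[Callable, Callable]:
    try:
        return ACTIVATIONS[name]
    except KeyError:
        raise ValueError(
            f"unknown activation {name!r}; choose from {sorted(ACTIVATIONS)}"
        ) from None


class DenseMLP:
    """A plain multi-layer perceptron with shared weights across the batch.

    Parameters
    ----------
    dims
        Layer sizes ``[d_in, h1, ..., d_out]``; at least ``[d_in, d_out]``.
    activation
        Name of the hidden nonlinearity (the output layer is affine).
    rng
        numpy Generator used for weight initialization (fan-in scaled
        Gaussian, zero biases).
    """

    def __init__(self, dims: list[int], activation: str = "elu", *,
                 rng: np.random.Generator):
        if len(dims) < 2 or any(d < 1 for d in dims):
            raise ValueError(f"invalid layer dims {dims}")
        self.dims = list(dims)
        self.activation = activation
        self._act, self._act_grad = get_activation(activation)
        self.weights: list[np.ndarray] = []
        self.biases: list[np.ndarray] = []
        for fan_in, fan_out in zip(dims[:-1], dims[1:]):
            w = rng.normal(0.0, 1.0 / np.sqrt(fan_in), size=(fan_out, fan_in))
            self.weights.append(w)
            self.biases.append(np.zeros(fan_out))

    @property
    def n_layers(self) -> int:
        return len(self.weights)

    @property
    def n_params(self) -> int:
        return sum(w.size + b.size for w, b in zip(self.weights, self.biases))

    def params(self) -> list[np.ndarray]:
        """Flat list of parameter arrays (references, not copies)."""
        out: list[np.ndarray] = []
        for w, b in zip(self.weights, self.biases):
            out.extend((w, b))
        return out

    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Evaluate the network on a batch ``x`` of shape (n, d_in).

        If ``cache`` is a list, per-layer ``(input, pre-activation)`` pairs are
        appended for use by :meth:`backward`.
        """
        a = np.asarray(x, dtype=float)
        last = self.n_layers - 1
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            u = a @ w.T + b
            if cache is not None:
                cache.append((a, u))
            a = self._act(u) if i < last else u
        return a

    def backward(self, cache: list, g_out: np.ndarray
                 ) -> tuple[np.ndarray, list[np.ndarray]]:
        """Backpropagate ``g_out`` (n, d_out) through a cached forward pass.

        Returns the gradient w.r.t. the input batch and a flat list of
        parameter gradients aligned with :meth:`params`.
        """
        last = self.n_layers - 1
        g = np.asarray(g_out, dtype=float)
        grads: list[np.ndarray | None] = [None] * (2 * self.n_layers)
        for i in range(last, -1, -1):
            a_prev, u = cache[i]
            if i < last:
                g = g * self._act_grad(u)
            grads[2 * i] = g.T @ a_prev
            grads[2 * i + 1] = g.sum(axis=0)
            g = g @ self.weights[i]
        return g, grads  # type: ignore[return-value]


class Adam:
    """Adaptive-moment gradient descent with decoupled weight decay.

    ``weight_decay`` is applied multiplicatively per step (AdamW style) to
    every parameter array whose index is in ``decay_mask`` (typically the
    weight matrices but not the biases).
    """

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8,
                 weight_decay: float = 0.0,
                 decay_mask: list[bool] | None = None):
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.weight_decay = weight_decay
        self.decay_mask = decay_mask or [p.ndim > 1 for p in params]
        self._m = [np.zeros_like(p) for p in params]
        self._v = [np.zeros_like(p) for p in params]
        self._t = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        self._t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1 ** self._t
        bias2 = 1.0 - b2 ** self._t
        for p, g, m, v, dec in zip(params, grads, self._m, self._v,
                                   self.decay_mask):
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            if dec and self.weight_decay:
                p *= 1.0 - self.lr * self.weight_decay
            p -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
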