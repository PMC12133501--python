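"""Minimal dense neural networks with hand-written backpropagation.

The control networks here are small multilayer perceptrons (a few
thousand parameters), so the package carries its own compact
forward/backward implementation on numpy arrays: dense layers, ELU and
tanh activations, and an Adam optimizer.  Each ``MLP.backward`` call
returns the gradient with respect to the *input* as well as accumulating
parameter gradients, which is what deterministic policy gradients need
(the actor update differentiates the critic with respect to the action).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def _elu(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, x, np.expm1(np.clip(x, None, 0.0)))


def _elu_grad(x: np.ndarray) -> np.ndarray:
    return np.where(x > 0, 1.0, np.exp(np.clip(x, None, 0.0)))


_ACTIVATIONS = {
    "elu": (_elu, _elu_grad),
    "tanh": (np.tanh, lambda x: 1.0 - np.tanh(x) ** 2),
    "linear": (lambda x: x, lambda x: np.ones_like(x)),
}


class MLP:
    """Fully connected network: sizes[0] -> ... -> sizes[-1].

    Hidden layers use ``hidden_activation``; the output layer uses
    ``output_activation``.  Weights use scaled-uniform (He-style) init,
    deterministic given ``rng``.
    """

    def __init__(
        self,
        sizes: list[int],
        rng: np.random.Generator,
        hidden_activation: str = "elu",
        output_activation: str = "linear",
    ) -> None:
        self.sizes = list(sizes)
        self.hidden_activation = hidden_activation
        self.output_activation = output_activation
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for n_in, n_out in zip(sizes[:-1], sizes[1:]):
            bound = np.sqrt(6.0 / n_in)
            self.W.append(rng.uniform(-bound, bound, size=(n_in, n_out)))
            self.b.append(np.zeros(n_out))
        self._cache: list[tuple[np.ndarray, np.ndarray]] | None = None

    # -- parameter plumbing --------------------------------------------------

    def parameters(self) -> list[np.ndarray]:
        return self.W + self.b

    def set_parameters(self, params: list[np.ndarray]) -> None:
        n = len(self.W)
        self.W = [p.copy() for p in params[:n]]
        self.b = [p.copy() for p in params[n:]]

    def copy_from(self, other: "MLP") -> None:
        self.set_parameters(other.parameters())

    # -- forward / backward --------------------------------------------------

    def _activation(self, layer: int) -> tuple:
        name = (
            self.output_activation
            if layer == len(self.W) - 1
            else self.hidden_activation
        )
        return _ACTIVATIONS[name]

    def forward(self, x: np.ndarray, cache: bool = False) -> np.ndarray:
        h = np.atleast_2d(np.asarray(x, dtype=float))
        caches = []
        for layer in range(len(self.W)):
            z = h @ self.W[layer] + self.b[layer]
            act, _ = self._activation(layer)
            caches.append((h, z))
            h = act(z)
        if cache:
            self._cache = caches
        return h

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return self.forward(x)

    def backward(self, dout: np.ndarray) -> np.ndarray:
        """Backpropagate dL/d(output); returns dL/d(input).

        Parameter gradients (averaged the way ``dout`` is scaled) are
        stored in ``self.grad_W`` / ``self.grad_b``.
        """
        if self._cache is None:
            raise RuntimeError("call forward(..., cache=True) before backward()")
        dout = np.atleast_2d(np.asarray(dout, dtype=float))
        self.grad_W = [np.zeros_like(w) for w in self.W]
        self.grad_b = [np.zeros_like(b) for b in self.b]
        grad = dout
        for layer in reversed(range(len(self.W))):
            h_in, z = self._cache[layer]
            _, act_grad = self._activation(layer)
            dz = grad * act_grad(z)
            self.grad_W[layer] = h_in.T @ dz
            self.grad_b[layer] = dz.sum(axis=0)
            grad = dz @ self.W[layer].T
        return grad

    def gradients(self) -> list[np.ndarray]:
        return self.grad_W + self.grad_b


@dataclass
class Adam:
    """Adam optimizer over a network's parameter list."""

    net: MLP
    lr: float = 3e-4
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8

    def __post_init__(self) -> None:
        params = self.net.parameters()
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray] | None = None) -> None:
        if grads is None:
            grads = self.net.gradients()
        params = self.net.parameters()
        self.t += 1
        lr_t = self.lr * np.sqrt(1 - self.beta2**self.t) / (1 - self.beta1**self.t)
        new_params = []
        for i, (p, g) in enumerate(zip(params, grads)):
            self.m[i] = self.beta1 * self.m[i] + (1 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1 - self.beta2) * g**2
            new_params.append(p - lr_t * self.m[i] / (np.sqrt(self.v[i]) + self.eps))
        self.net.set_parameters(new_params)
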