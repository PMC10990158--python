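"""Small fully connected building blocks and the Adam optimizer.

Only what the compression channels, decoders and set predictors need; all
parameters are float64 and initialization is driven by an explicit
``numpy.random.Generator`` so training runs are reproducible.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np

from ._autograd import Parameter, Tensor

__all__ = ["Linear", "MLP", "Adam"]


class Linear:
    """Affine layer ``x @ W + b`` with Glorot or zero initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator, zero_init: bool = False):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            scale = np.sqrt(2.0 / (n_in + n_out))
            w = rng.normal(0.0, scale, size=(n_in, n_out))
        self.W = Parameter(w)
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    @property
    def parameters(self):
        return [self.W, self.b]


class MLP:
    """Small multilayer perceptron; the output head may start at zero.

    Zero-initializing the head pins the initial output to the bias (zero),
    which is how channels start exactly at the prior.  Activation is tanh
    by default; relu is available.
    """

    def __init__(
        self,
        n_in: int,
        hidden: Sequence[int],
        n_out: int,
        rng: np.random.Generator,
        zero_init_head: bool = False,
        activation: str = "tanh",
    ):
        if activation not in ("tanh", "relu"):
            raise ValueError("activation must be 'tanh' or 'relu'")
        self.activation = activation
        self.layers = []
        d = n_in
        for h in hidden:
            self.layers.append(Linear(d, h, rng))
            d = h
        self.head = Linear(d, n_out, rng, zero_init=zero_init_head)

    def __call__(self, x: Tensor) -> Tensor:
        for layer in self.layers:
            x = layer(x)
            x = x.tanh() if self.activation == "tanh" else x.relu()
        return self.head(x)

    @property
    def parameters(self):
        ps = []
        for layer in self.layers:
            ps.extend(layer.parameters)
        ps.extend(self.head.parameters)
        return ps


class Adam:
    """Adam with bias correction; operates in place on Parameter tensors."""

    def __init__(self, params, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g**2
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
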