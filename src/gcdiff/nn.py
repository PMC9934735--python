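"""Small neural-network building blocks on top of :mod:`gcdiff.autodiff`."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, concat


class Linear:
    """Affine map ``x @ W + b`` with variance-scaled initialization."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 zero_init: bool = False, name: str = ""):
        if zero_init:
            w = np.zeros((n_in, n_out))
        else:
            w = rng.normal(0.0, 1.0 / np.sqrt(n_in), size=(n_in, n_out))
        self.W = Tensor(w, requires_grad=True, name=f"{name}.W")
        self.b = Tensor(np.zeros(n_out), requires_grad=True, name=f"{name}.b")

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class MLP:
    """Two-layer perceptron with SiLU activations."""

    def __init__(self, n_in: int, n_hidden: int, n_out: int,
                 rng: np.random.Generator, zero_init_last: bool = False,
                 name: str = ""):
        self.l1 = Linear(n_in, n_hidden, rng, name=f"{name}.l1")
        self.l2 = Linear(n_hidden, n_out, rng, zero_init=zero_init_last,
                         name=f"{name}.l2")

    def __call__(self, x: Tensor) -> Tensor:
        return self.l2(self.l1(x).silu())

    def parameters(self):
        return self.l1.parameters() + self.l2.parameters()


class LayerNorm:
    """Per-row normalization with learned scale and shift."""

    def __init__(self, dim: int, name: str = ""):
        self.gamma = Tensor(np.ones(dim), requires_grad=True, name=f"{name}.g")
        self.beta = Tensor(np.zeros(dim), requires_grad=True, name=f"{name}.b")
        self.eps = 1e-6

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta

    def parameters(self):
        return [self.gamma, self.beta]


class Adam:
    """Adam optimizer over a flat parameter list."""

    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def state_dict(self):
        return {"t": self.t, "m": self.m, "v": self.v}

    def load_state_dict(self, state):
        self.t = int(state["t"])
        self.m = [np.array(a) for a in state["m"]]
        self.v = [np.array(a) for a in state["v"]]
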