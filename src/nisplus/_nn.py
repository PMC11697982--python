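"""Small neural-network toolkit (linear layers, MLPs, Adam) on the autodiff core."""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor

__all__ = ["Linear", "MLP", "ResidualMLP", "Adam"]


class Linear:
    def __init__(self, fan_in: int, fan_out: int, rng: np.random.Generator,
                 zero_init: bool = False):
        if zero_init:
            w = np.zeros((fan_in, fan_out))
        else:
            w = rng.normal(0.0, np.sqrt(1.0 / fan_in), size=(fan_in, fan_out))
        self.W = Tensor(w, requires_grad=True)
        self.b = Tensor(np.zeros(fan_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self):
        return [self.W, self.b]


class MLP:
    """Fully connected network with tanh hidden activations.

    `zero_last=True` zero-initializes the output layer so the network starts
    as the zero map (used for identity-starting couplings and dynamics).
    """

    def __init__(self, sizes, rng: np.random.Generator, zero_last: bool = False):
        self.sizes = list(sizes)
        self.layers = []
        for i, (a, b) in enumerate(zip(sizes[:-1], sizes[1:])):
            last = i == len(sizes) - 2
            self.layers.append(Linear(a, b, rng, zero_init=zero_last and last))

    def __call__(self, x: Tensor) -> Tensor:
        for i, lin in enumerate(self.layers):
            x = lin(x)
            if i < len(self.layers) - 1:
                x = x.tanh()
        return x

    def forward_np(self, x: np.ndarray) -> np.ndarray:
        """Plain-numpy forward pass (no graph)."""
        a = np.asarray(x, dtype=np.float64)
        for i, lin in enumerate(self.layers):
            a = a @ lin.W.data + lin.b.data
            if i < len(self.layers) - 1:
                a = np.tanh(a)
        return a

    def jacobian_batch(self, x: np.ndarray) -> np.ndarray:
        """Analytic Jacobians, shape (B, d_out, d_in)."""
        a = np.atleast_2d(np.asarray(x, dtype=np.float64))
        B, d0 = a.shape
        J = np.broadcast_to(np.eye(d0), (B, d0, d0)).copy()  # (B, in, cur)
        for i, lin in enumerate(self.layers):
            pre = a @ lin.W.data + lin.b.data
            J = J @ lin.W.data
            if i < len(self.layers) - 1:
                a = np.tanh(pre)
                J = J * (1.0 - a * a)[:, None, :]
            else:
                a = pre
        return J.transpose(0, 2, 1)

    def parameters(self):
        return [p for lin in self.layers for p in lin.parameters()]


class ResidualMLP:
    """Map y + net(y); identity at initialization when net is zero-initialized."""

    def __init__(self, dim: int, hidden: int, rng: np.random.Generator,
                 n_hidden: int = 2):
        sizes = [dim] + [hidden] * n_hidden + [dim]
        self.dim = dim
        self.net = MLP(sizes, rng, zero_last=True)

    def __call__(self, y: Tensor) -> Tensor:
        return y + self.net(y)

    def forward_np(self, y: np.ndarray) -> np.ndarray:
        y = np.asarray(y, dtype=np.float64)
        return y + self.net.forward_np(y)

    def jacobian_batch(self, y: np.ndarray) -> np.ndarray:
        J = self.net.jacobian_batch(y)
        return J + np.eye(self.dim)

    def parameters(self):
        return self.net.parameters()


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
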