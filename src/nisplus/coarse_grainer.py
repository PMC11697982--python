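"""Invertible coarse-graining encoder.

The coarse-graining map phi projects a micro-state x in R^p to a macro-state
y in R^q by sending x through a stack of exactly invertible affine coupling
layers psi and keeping the first q output coordinates ("information
discarding").  The anti-coarse-graining map phi-dagger shares all parameters
with phi: a macro-state is decoded by padding the discarded p-q coordinates
with standard-normal noise and applying psi inverse.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor, concat
from ._nn import MLP


@dataclass
class EncoderSpec:
    """Hyperparameters of the invertible encoder."""

    p: int
    q: int
    n_coupling_layers: int = 3
    hidden_width: int = 32
    init_seed: int = 0

    def __post_init__(self):
        if not 1 <= self.q <= self.p:
            raise ValueError(f"require 1 <= q <= p, got q={self.q}, p={self.p}")
        if self.n_coupling_layers < 1:
            raise ValueError("n_coupling_layers must be >= 1")


class AffineCoupling:
    """RealNVP-style affine coupling layer on R^p.

    One half of the coordinates passes through unchanged and parameterizes
    an affine transform (scale and shift) of the other half.  The scale head
    is squashed through s_max*tanh so conditioning stays bounded; both heads
    are zero-initialized, so the layer starts as the identity.
    """

    S_MAX = 5.0

    def __init__(self, p: int, keep_idx: np.ndarray, change_idx: np.ndarray,
                 hidden: int, rng: np.random.Generator):
        self.p = p
        self.keep = np.asarray(keep_idx, dtype=int)
        self.change = np.asarray(change_idx, dtype=int)
        perm = np.concatenate([self.keep, self.change])
        self.inv_perm = np.argsort(perm)
        k, c = len(self.keep), len(self.change)
        self.s_net = MLP([k, hidden, c], rng, zero_last=True)
        self.t_net = MLP([k, hidden, c], rng, zero_last=True)

    def _heads(self, xa: Tensor):
        s = self.s_net(xa).tanh() * self.S_MAX
        t = self.t_net(xa)
        return s, t

    def forward(self, x: Tensor) -> Tensor:
        xa = x.take_columns(self.keep)
        xb = x.take_columns(self.change)
        s, t = self._heads(xa)
        yb = xb * s.exp() + t
        return concat([xa, yb], axis=1).take_columns(self.inv_perm)

    def inverse(self, y: Tensor) -> Tensor:
        ya = y.take_columns(self.keep)
        yb = y.take_columns(self.change)
        s, t = self._heads(ya)
        xb = (yb - t) * (-s).exp()
        return concat([ya, xb], axis=1).take_columns(self.inv_perm)

    def log_det(self, x: Tensor) -> Tensor:
        """log |det J| of the forward map, one value per row."""
        s, _ = self._heads(x.take_columns(self.keep))
        return s.sum(axis=1)

    def parameters(self):
        return self.s_net.parameters() + self.t_net.parameters()


class InvertibleEncoder:
    """Bijection psi: R^p -> R^p with projection-based coarse graining.

    psi is a fixed volume-preserving affine pre-rotation (centering plus an
    orthogonal matrix, typically the PCA rotation of the training data)
    followed by a stack of learnable affine coupling layers.  The rotation
    lets the identity-initialized couplings start from macro coordinates
    aligned with the dominant directions of variation.
    """

    def __init__(self, spec: EncoderSpec):
        self.spec = spec
        p, q = spec.p, spec.q
        self.p, self.q = p, q
        rng = np.random.default_rng(spec.init_seed)
        even = np.arange(0, p, 2)
        odd = np.arange(1, p, 2)
        if p == 1:
            raise ValueError("coupling layers require p >= 2")
        self.center = np.zeros(p)
        self.rotation = np.eye(p)
        self.layers = []
        for i in range(spec.n_coupling_layers):
            keep, change = (even, odd) if i % 2 == 0 else (odd, even)
            self.layers.append(
                AffineCoupling(p, keep, change, spec.hidden_width, rng)
            )

    def set_prerotation(self, center: np.ndarray, rotation: np.ndarray) -> None:
        """Install the fixed affine pre-layer x -> (x - center) @ rotation."""
        center = np.asarray(center, dtype=np.float64).ravel()
        rotation = np.asarray(rotation, dtype=np.float64)
        if center.shape != (self.p,) or rotation.shape != (self.p, self.p):
            raise ValueError("pre-rotation shape mismatch")
        if not np.allclose(rotation @ rotation.T, np.eye(self.p), atol=1e-8):
            raise ValueError("pre-rotation must be orthogonal")
        self.center = center
        self.rotation = rotation

    def fit_prerotation(self, X: np.ndarray) -> None:
        """Set the pre-layer to the PCA rotation of the sample X (n, p)."""
        X = np.asarray(X, dtype=np.float64)
        center = X.mean(axis=0)
        cov = np.cov(X - center, rowvar=False)
        evals, evecs = np.linalg.eigh(np.atleast_2d(cov))
        order = np.argsort(evals)[::-1]
        Q = evecs[:, order]
        # deterministic sign: largest-magnitude loading positive
        for j in range(Q.shape[1]):
            k = np.argmax(np.abs(Q[:, j]))
            if Q[k, j] < 0:
                Q[:, j] = -Q[:, j]
        self.set_prerotation(center, Q)

    # -- graph-building (training) paths --------------------------------
    def psi(self, x: Tensor) -> Tensor:
        x = (x - Tensor(self.center)) @ Tensor(self.rotation)
        for layer in self.layers:
            x = layer.forward(x)
        return x

    def psi_inv(self, z: Tensor) -> Tensor:
        for layer in reversed(self.layers):
            z = layer.inverse(z)
        return z @ Tensor(self.rotation.T) + Tensor(self.center)

    def encode_t(self, x: Tensor) -> Tensor:
        return self.psi(x).take_columns(np.arange(self.q))

    def decode_t(self, y: Tensor, xi: np.ndarray | None) -> Tensor:
        if self.q == self.p:
            return self.psi_inv(y)
        z = concat([y, Tensor(xi)], axis=1)
        return self.psi_inv(z)

    # -- numpy convenience paths -----------------------------------------
    def _as_batch(self, x, dim: int):
        x = np.asarray(x, dtype=np.float64)
        single = x.ndim == 1
        x = np.atleast_2d(x)
        if x.shape[1] != dim:
            raise ValueError(
                f"input has dimension {x.shape[1]}, expected {dim}"
            )
        if not np.all(np.isfinite(x)):
            raise ValueError("input contains non-finite values")
        return x, single

    def encode(self, x) -> np.ndarray:
        """phi: micro-state(s) -> macro-state(s), first q coordinates of psi."""
        xb, single = self._as_batch(x, self.p)
        y = self.encode_t(Tensor(xb)).data
        return y[0] if single else y

    def decode(self, y, noise_seed: int = 0) -> np.ndarray:
        """phi-dagger: macro-state(s) -> micro-state(s), noise-padded inverse."""
        yb, single = self._as_batch(y, self.q)
        if self.q == self.p:
            xi = None
        else:
            rng = np.random.default_rng(noise_seed)
            xi = rng.standard_normal((yb.shape[0], self.p - self.q))
        x = self.decode_t(Tensor(yb), xi).data
        return x[0] if single else x

    def jacobian(self, x) -> np.ndarray:
        """Encoder Jacobian d phi / d x at a micro-state, shape (q, p)."""
        xb, _ = self._as_batch(x, self.p)
        if xb.shape[0] != 1:
            raise ValueError("jacobian expects a single micro-state")
        rows = []
        for k in range(self.q):
            xt = Tensor(xb, requires_grad=True)
            y = self.encode_t(xt)
            seed = np.zeros_like(y.data)
            seed[0, k] = 1.0
            y.backward(seed)
            rows.append(xt.grad[0].copy())
        J = np.stack(rows)
        if not np.all(np.isfinite(J)):
            raise FloatingPointError("non-finite encoder Jacobian")
        return J

    def log_det_psi(self, x) -> np.ndarray:
        """log |det J_psi| per row (sum of coupling-layer scale factors)."""
        xb, single = self._as_batch(x, self.p)
        t = (Tensor(xb) - Tensor(self.center)) @ Tensor(self.rotation)
        total = np.zeros(xb.shape[0])  # orthogonal pre-layer adds 0
        for layer in self.layers:
            total += layer.log_det(t).data
            t = layer.forward(t)
        return total[0] if single else total

    def parameters(self):
        return [p for layer in self.layers for p in layer.parameters()]

    # -- checkpointing ----------------------------------------------------
    def state_arrays(self) -> list[np.ndarray]:
        return ([self.center.copy(), self.rotation.copy()]
                + [p.data.copy() for p in self.parameters()])

    def load_state_arrays(self, arrays) -> None:
        params = self.parameters()
        if len(arrays) != len(params) + 2:
            raise ValueError("checkpoint parameter count mismatch")
        self.center = np.asarray(arrays[0], dtype=np.float64)
        self.rotation = np.asarray(arrays[1], dtype=np.float64)
        for p, a in zip(params, arrays[2:]):
            p.data[...] = a


def encode(mapping: InvertibleEncoder, x):
    return mapping.encode(x)


def decode(mapping: InvertibleEncoder, y, noise_seed: int = 0):
    return mapping.decode(y, noise_seed=noise_seed)


def encoder_jacobian(mapping: InvertibleEncoder, x):
    return mapping.jacobian(x)
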