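"""Forward and reversed macro-dynamics, micro prediction and rollout.

The forward map f advances a macro-state one step; the reversed map g is
trained to take a macro-state one step back and is what makes effective
information maximization trainable.  Both are residual MLPs (y + net(y))
with zero-initialized output heads, so an untrained pair is the identity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._nn import ResidualMLP

__all__ = ["DynamicsPair", "RolloutResult", "forward_step", "reverse_step",
           "predict_micro", "rollout"]

_OVERFLOW_GUARD = 1e8


@dataclass
class DynamicsPair:
    """Learnable one-step forward (f) and reverse (g) macro-dynamics."""

    f: ResidualMLP
    g: ResidualMLP
    q: int

    @classmethod
    def create(cls, q: int, hidden: int, rng: np.random.Generator) -> "DynamicsPair":
        return cls(f=ResidualMLP(q, hidden, rng), g=ResidualMLP(q, hidden, rng), q=q)

    def parameters(self):
        return self.f.parameters() + self.g.parameters()


def _step(net: ResidualMLP, y, q: int) -> np.ndarray:
    y = np.asarray(y, dtype=np.float64)
    single = y.ndim == 1
    yb = np.atleast_2d(y)
    if yb.shape[1] != q:
        raise ValueError(f"macro-state has dimension {yb.shape[1]}, expected {q}")
    if not np.all(np.isfinite(yb)):
        raise ValueError("non-finite macro-state")
    out = net.forward_np(yb)
    if not np.all(np.isfinite(out)):
        raise FloatingPointError("macro-dynamics diverged to non-finite values")
    return out[0] if single else out


def forward_step(d: DynamicsPair, y_t) -> np.ndarray:
    """One macro time step forward: y_t -> y_{t+1}."""
    return _step(d.f, y_t, d.q)


def reverse_step(d: DynamicsPair, y_next) -> np.ndarray:
    """One macro time step backward: y_{t+1} -> y_t."""
    return _step(d.g, y_next, d.q)


def predict_micro(model, x_t, noise_seed: int = 0) -> np.ndarray:
    """One-step micro prediction: decode(f(encode(x_t)))."""
    enc, dyn = model.encoder_, model.dynamics_
    y = enc.encode(x_t)
    y_next = forward_step(dyn, y)
    return enc.decode(y_next, noise_seed=[noise_seed, 0])


@dataclass
class RolloutResult:
    """Multi-step micro prediction; `diverged` marks a truncated rollout."""

    states: np.ndarray  # (steps, p)
    diverged: bool = False

    def __len__(self):
        return len(self.states)


def rollout(model, x_0, steps: int, noise_seed: int = 0) -> RolloutResult:
    """Iterate the macro-dynamics from encode(x_0), decoding every step.

    The trajectory is rolled out entirely in macro space (a single encode);
    each predicted macro-state is decoded with its own deterministic noise
    stream, so a k-step rollout restricted to its first j steps equals the
    j-step rollout under the same seed.
    """
    if steps < 1:
        raise ValueError("steps must be >= 1")
    enc, dyn = model.encoder_, model.dynamics_
    y = enc.encode(np.asarray(x_0, dtype=np.float64))
    out, diverged = [], False
    for i in range(steps):
        y = forward_step(dyn, y)
        if np.max(np.abs(y)) > _OVERFLOW_GUARD:
            diverged = True
            break
        out.append(enc.decode(y, noise_seed=[noise_seed, i]))
    states = np.asarray(out) if out else np.empty((0, enc.p))
    return RolloutResult(states=states, diverged=diverged)
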