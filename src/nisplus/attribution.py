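"""Integrated-gradients attribution of macro-dimensions to micro-dimensions.

For each learned macro coordinate phi_k the integrated gradient against a
baseline b is

    IG_kj = (x_j - b_j) * integral_0^1 d phi_k / d x_j (b + a (x - b)) da,

approximated on the straight-line path with a trapezoidal rule.  The row
sums then satisfy the completeness identity
sum_j IG_kj = phi_k(x) - phi_k(b) up to quadrature error, which makes the
map an exact budget of how much each micro coordinate moved the macro one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autodiff import Tensor

__all__ = ["AttributionMap", "integrated_gradients", "aggregate_saliency"]


@dataclass
class AttributionMap:
    values: np.ndarray  # (q, p)
    baseline: np.ndarray
    n_steps: int
    normalized: bool = False


def integrated_gradients(encoder, x, baseline=None, n_steps: int = 64) -> AttributionMap:
    """Attribute each macro coordinate of `encoder` to the micro coordinates.

    `encoder` is an InvertibleEncoder (or anything with encode_t/p/q);
    `baseline` defaults to the zero vector.
    """
    if n_steps < 8:
        raise ValueError("n_steps must be >= 8")
    x = np.asarray(x, dtype=np.float64).ravel()
    p, q = encoder.p, encoder.q
    if x.shape[0] != p:
        raise ValueError(f"input has dimension {x.shape[0]}, expected {p}")
    baseline = (np.zeros(p) if baseline is None
                else np.asarray(baseline, dtype=np.float64).ravel())
    if baseline.shape[0] != p:
        raise ValueError("baseline dimension mismatch")
    alphas = np.linspace(0.0, 1.0, n_steps)
    # trapezoid weights summing to 1
    w = np.full(n_steps, 1.0 / (n_steps - 1))
    w[0] = w[-1] = 0.5 / (n_steps - 1)
    path = baseline + alphas[:, None] * (x - baseline)
    rows = []
    for k in range(q):
        xt = Tensor(path, requires_grad=True)
        y = encoder.encode_t(xt)
        seed = np.zeros_like(y.data)
        seed[:, k] = w
        y.backward(seed)
        if not np.all(np.isfinite(xt.grad)):
            raise FloatingPointError("non-finite gradient during attribution")
        rows.append(xt.grad.sum(axis=0))
    values = np.stack(rows) * (x - baseline)
    return AttributionMap(values=values, baseline=baseline, n_steps=n_steps)


def aggregate_saliency(maps, drop_dims=(), normalize: bool = False) -> np.ndarray:
    """Mean absolute attribution over samples, with optional column drops.

    `drop_dims` columns (e.g. velocity coordinates) are zeroed before the
    optional per-row max-abs normalization.
    """
    maps = list(maps)
    if not maps:
        raise ValueError("empty collection of attribution maps")
    vals = np.mean([np.abs(m.values) for m in maps], axis=0)
    drop = np.asarray(list(drop_dims), dtype=int)
    if drop.size:
        vals[:, drop] = 0.0
    if normalize:
        mx = np.abs(vals).max(axis=1, keepdims=True)
        mx[mx == 0] = 1.0
        vals = vals / mx
    return vals
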