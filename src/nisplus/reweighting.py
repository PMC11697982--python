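"""Inverse-probability reweighting toward a uniform macro-state distribution.

The training objective needs expectations under the do-intervention
do(y ~ Uniform) while the data follow the observational density p(y).
Each sample therefore gets weight w_i proportional to 1 / p_hat(y_i): the
uniform target density is constant over the support box and cancels into
the normalization.  p_hat is a Gaussian kernel density estimate.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import gaussian_kde

__all__ = ["WeightSet", "estimate_density", "compute_weights"]

_VAR_FLOOR = 1e-6


@dataclass
class WeightSet:
    """Self-normalized (mean 1) positive weights aligned to samples."""

    weights: np.ndarray
    bandwidth: float | str
    support_box: np.ndarray = field(repr=False)  # (2, q): min row, max row
    clip_max: float = 20.0

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if np.any(self.weights <= 0):
            raise ValueError("weights must be positive")

    def to_csv(self, path) -> None:
        np.savetxt(path, self.weights, header="weight", comments="")


def _prep_samples(y_samples: np.ndarray) -> np.ndarray:
    y = np.asarray(y_samples, dtype=np.float64)
    if y.ndim == 1:
        y = y[:, None]
    if not np.all(np.isfinite(y)):
        raise ValueError("samples contain non-finite values")
    return y


def estimate_density(y_samples, bandwidth="auto"):
    """Gaussian KDE of the macro-state distribution.

    Returns a callable evaluating the density at (m, q) points.  `bandwidth`
    is either "auto" (Scott's rule) or a positive real used as the kernel
    bandwidth factor.  Zero-variance dimensions are jittered at a small
    floor so the kernel covariance stays non-singular.
    """
    y = _prep_samples(y_samples)
    n, q = y.shape
    if n < 2:
        raise ValueError("need at least two samples for density estimation")
    stds = y.std(axis=0)
    if np.any(stds < _VAR_FLOOR):
        warnings.warn(
            "zero-variance macro dimension: applying bandwidth floor",
            RuntimeWarning,
        )
        rng = np.random.default_rng(0)
        y = y + rng.standard_normal(y.shape) * _VAR_FLOOR
    bw = "scott" if bandwidth == "auto" else float(bandwidth)
    kde = gaussian_kde(y.T, bw_method=bw)

    def density(points):
        pts = _prep_samples(points)
        return kde(pts.T)

    density.kde = kde
    return density


def compute_weights(y_samples, bandwidth="auto", clip_max: float = 20.0) -> WeightSet:
    """Inverse-density weights emulating a uniform intervention on y.

    Weights are clipped at `clip_max` and self-normalized to mean 1; the
    clip/normalize pair is iterated to its joint fixed point.
    """
    y = _prep_samples(y_samples)
    box = np.vstack([y.min(axis=0), y.max(axis=0)])
    if y.shape[0] == 1:
        return WeightSet(np.array([1.0]), bandwidth, box, clip_max)
    if np.allclose(y, y[0]):
        warnings.warn("all samples identical: uniform weights", RuntimeWarning)
        return WeightSet(np.ones(y.shape[0]), bandwidth, box, clip_max)
    dens = estimate_density(y, bandwidth)
    p = np.clip(dens(y), 1e-300, None)
    w = 1.0 / p
    w /= w.mean()
    for _ in range(100):
        w_clipped = np.minimum(w, clip_max)
        w_next = w_clipped / w_clipped.mean()
        if np.max(np.abs(w_next - w)) < 1e-12:
            w = w_next
            break
        w = w_next
    return WeightSet(w, bandwidth, box, clip_max)
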