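"""Effective information (EI) measures and the causal-emergence degree.

EI is the mutual information between a system's state and its next state
when the current state is forced, by intervention, to be uniformly
distributed.  For a discrete Markov chain with transition matrix P this is
exact:

    EI = H(mean of rows) - mean of row entropies.

For a learned continuous dynamics f: R^q -> R^q with additive Gaussian
output noise, a uniform intervention on the box prod_i [-L_i, L_i] gives

    EI = E[ln |det J_f(y)|] + sum_i ln(2 L_i) - (q/2) ln(2 pi e)
         - sum_i ln sigma_i

in nats, with the expectation estimated by Monte Carlo.  The dimension
averaged EI, J = EI / q, makes dynamics of different dimensionality
comparable; the degree of causal emergence is Delta-J = J(macro) - J(micro).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import entropy as _shannon_entropy
from sklearn.metrics import mutual_info_score

__all__ = [
    "TransitionMatrix",
    "Partition",
    "ContinuousEIEstimate",
    "CEReport",
    "ei_discrete",
    "coarse_grain_tpm",
    "ei_continuous_mc",
    "delta_j",
    "psi_indicator",
]

_ROW_TOL = 1e-9


@dataclass
class TransitionMatrix:
    """Row-stochastic n x n matrix: row i = P(next state | current state i)."""

    probs: np.ndarray
    state_labels: list | None = None

    def __post_init__(self):
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 2 or self.probs.shape[0] != self.probs.shape[1]:
            raise ValueError("transition matrix must be square")
        if self.probs.shape[0] < 1:
            raise ValueError("transition matrix needs at least one state")
        if np.any(self.probs < -_ROW_TOL) or np.any(self.probs > 1 + _ROW_TOL):
            raise ValueError("transition probabilities must lie in [0, 1]")
        sums = self.probs.sum(axis=1)
        bad = np.flatnonzero(np.abs(sums - 1.0) > _ROW_TOL)
        if bad.size:
            raise ValueError(
                f"row {bad[0]} sums to {sums[bad[0]]:.12g}, not 1"
            )

    @property
    def n(self) -> int:
        return self.probs.shape[0]


@dataclass
class Partition:
    """Disjoint groups of micro-state indices covering 0..n-1."""

    groups: list

    def __post_init__(self):
        self.groups = [np.asarray(sorted(g), dtype=int) for g in self.groups]
        if any(len(g) == 0 for g in self.groups):
            raise ValueError("empty group in partition")

    def validate_for(self, n: int) -> None:
        allidx = np.concatenate(self.groups)
        if len(set(allidx.tolist())) != len(allidx):
            raise ValueError("partition groups overlap")
        if sorted(allidx.tolist()) != list(range(n)):
            raise ValueError(f"partition does not cover states 0..{n - 1}")


@dataclass
class ContinuousEIEstimate:
    """Monte-Carlo EI of a continuous dynamics (natural log)."""

    ei_total: float
    j_dim_avg: float
    mc_samples: int
    mc_stderr: float
    range_L: float
    noise_sigmas: np.ndarray = field(repr=False, default=None)


@dataclass
class CEReport:
    """Causal-emergence record at one macro scale q."""

    q: int
    j_macro: float
    j_micro: float
    delta_j: float
    nmae: float
    valid: bool
    threshold: float = 0.3

    def to_dict(self) -> dict:
        return {
            "q": int(self.q),
            "j_macro": float(self.j_macro),
            "j_micro": float(self.j_micro),
            "delta_j": float(self.delta_j),
            "nmae": float(self.nmae),
            "valid": bool(self.valid),
            "threshold": float(self.threshold),
        }


def _check_base(log_base: float) -> float:
    if log_base <= 0 or log_base == 1:
        raise ValueError(f"log_base must be positive and != 1, got {log_base}")
    return float(log_base)


def ei_discrete(tpm: TransitionMatrix | np.ndarray, log_base: float = 2.0) -> float:
    """Effective information of a discrete Markov chain.

    Equals I(X; Y) for the channel Y | X = row_X with X uniform over states.
    """
    if not isinstance(tpm, TransitionMatrix):
        tpm = TransitionMatrix(np.asarray(tpm))
    base = _check_base(log_base)
    rows = tpm.probs
    mean_row = rows.mean(axis=0)
    h_out = _shannon_entropy(mean_row, base=base)
    h_rows = np.array([_shannon_entropy(r, base=base) for r in rows])
    return float(h_out - h_rows.mean())


def coarse_grain_tpm(tpm: TransitionMatrix | np.ndarray,
                     partition: Partition) -> TransitionMatrix:
    """Group-average a transition matrix onto macro-states.

    Macro entry (A, B) is the mean over micro states i in A of the total
    probability of jumping into B (uniform weighting inside each group).
    """
    if not isinstance(tpm, TransitionMatrix):
        tpm = TransitionMatrix(np.asarray(tpm))
    partition.validate_for(tpm.n)
    m = len(partition.groups)
    macro = np.empty((m, m))
    for a, ga in enumerate(partition.groups):
        block = tpm.probs[ga]
        for b, gb in enumerate(partition.groups):
            macro[a, b] = block[:, gb].sum(axis=1).mean()
    return TransitionMatrix(macro)


def _numeric_jacobians(f, ys: np.ndarray, h: float = 1e-5) -> np.ndarray:
    n, q = ys.shape
    J = np.empty((n, q, q))
    for j in range(q):
        e = np.zeros(q)
        e[j] = h
        J[:, :, j] = (np.asarray(f(ys + e)) - np.asarray(f(ys - e))) / (2 * h)
    return J


def ei_continuous_mc(f, noise_sigmas, range_L: float, mc_samples: int = 1000,
                     seed: int = 0, q: int | None = None) -> ContinuousEIEstimate:
    """Monte-Carlo EI of a differentiable map with Gaussian output noise.

    `f` maps a batch (n, q) to (n, q); if it exposes `jacobian_batch`, the
    analytic Jacobians are used, otherwise central finite differences.
    Singular values of the Jacobian are floored at 1e-12, so a degenerate
    map yields a large negative (never non-finite) EI.
    """
    if mc_samples < 1:
        raise ValueError("mc_samples must be >= 1")
    sig = np.atleast_1d(np.asarray(noise_sigmas, dtype=np.float64))
    if np.any(sig <= 0):
        raise ValueError("noise_sigmas must be positive")
    q = len(sig) if q is None else int(q)
    L = np.broadcast_to(np.asarray(range_L, dtype=np.float64), (q,))
    if np.any(L <= 0):
        raise ValueError("range_L must be positive")
    rng = np.random.default_rng(seed)
    ys = rng.uniform(-L, L, size=(mc_samples, q))
    if hasattr(f, "jacobian_batch"):
        J = np.asarray(f.jacobian_batch(ys))
    else:
        J = _numeric_jacobians(f, ys)
    if not np.all(np.isfinite(J)):
        raise FloatingPointError("non-finite Jacobian during EI estimation")
    sv = np.linalg.svd(J, compute_uv=False)
    logdets = np.log(np.clip(sv, 1e-12, None)).sum(axis=1)
    mean_logdet = float(logdets.mean())
    stderr = float(logdets.std(ddof=1) / np.sqrt(mc_samples)) if mc_samples > 1 else 0.0
    ei = (mean_logdet + np.log(2 * L).sum()
          - 0.5 * q * np.log(2 * np.pi * np.e) - np.log(sig).sum())
    return ContinuousEIEstimate(
        ei_total=float(ei),
        j_dim_avg=float(ei / q),
        mc_samples=int(mc_samples),
        mc_stderr=stderr,
        range_L=range_L if np.isscalar(range_L) else np.asarray(range_L, float),
        noise_sigmas=sig,
    )


def delta_j(j_macro: float, j_micro: float) -> float:
    """Degree of causal emergence: Delta-J = J(macro) - J(micro)."""
    if not (np.isfinite(j_macro) and np.isfinite(j_micro)):
        raise ValueError("delta_j requires finite inputs")
    return float(j_macro - j_micro)


# ----------------------------------------------------------------------
# Psi emergence indicator
# ----------------------------------------------------------------------

def _mi_discrete(a: np.ndarray, b: np.ndarray) -> float:
    return mutual_info_score(a, b) / np.log(2)


def _mi_gaussian(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 0.0
    rho = np.clip(np.corrcoef(a, b)[0, 1], -0.999999, 0.999999)
    return float(-0.5 * np.log2(1.0 - rho * rho))


def _mi_binned(a: np.ndarray, b: np.ndarray, bins: int = 16) -> float:
    counts, _, _ = np.histogram2d(a, b, bins=bins)
    p = counts / counts.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    mask = p > 0
    return float((p[mask] * np.log2(p[mask] / (px @ py)[mask])).sum())


_MI_ESTIMATORS = {
    "discrete": _mi_discrete,
    "gaussian": _mi_gaussian,
    "binned": _mi_binned,
}


def psi_indicator(micro: np.ndarray, macro_v: np.ndarray,
                  mi_estimator: str = "auto") -> float:
    """Approximate synergy-based emergence indicator, in bits.

    Psi = I(V_t; V_{t+1}) - sum_j I(x_t^(j); V_{t+1}).  Positive Psi is a
    sufficient (not necessary) signature of emergence of the macro variable
    V over the micro variables x.
    """
    micro = np.asarray(micro)
    macro_v = np.asarray(macro_v, dtype=np.float64).ravel()
    if micro.ndim != 2:
        raise ValueError("micro must be a T x p array")
    if len(macro_v) != micro.shape[0]:
        raise ValueError("micro and macro_v must be time-aligned")
    if len(macro_v) < 2:
        raise ValueError("need at least two time steps")
    if mi_estimator == "auto":
        vals = np.unique(micro)
        discrete = vals.size <= 32 and np.allclose(vals, np.round(vals))
        mi_estimator = "discrete" if discrete else "gaussian"
    try:
        mi = _MI_ESTIMATORS[mi_estimator]
    except KeyError:
        raise ValueError(f"unknown mi_estimator {mi_estimator!r}") from None
    if mi_estimator != "discrete" and np.std(macro_v) == 0:
        warnings.warn("constant macro variable: Psi is 0", RuntimeWarning)
        return 0.0
    if mi_estimator == "discrete":
        # factorize continuous-looking values into integer labels
        def lab(x):
            return np.unique(x, return_inverse=True)[1]
    else:
        def lab(x):
            return x
    v_now, v_next = lab(macro_v[:-1]), lab(macro_v[1:])
    psi = mi(v_now, v_next)
    for j in range(micro.shape[1]):
        psi -= mi(lab(micro[:-1, j]), v_next)
    return float(psi)
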