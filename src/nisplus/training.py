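"""End-to-end NIS+ training and causal-emergence quantification.

The estimator jointly learns an invertible coarse-graining encoder phi, a
forward macro-dynamics f and a reversed macro-dynamics g by minimizing

    sum_t w(x_t) ||phi(x_t) - g(phi(x_{t+1}))||_1
        + lambda ||phi_dagger(f(phi(x_t))) - x_{t+1}||_1,

where the inverse-probability weights w re-target the macro-state
distribution to uniform (the do-intervention surrogate) and lambda is the
Lagrange multiplier of the micro-prediction constraint.  Training tracks
the dimension-averaged effective information J of the learned macro
dynamics each epoch; comparing J across macro dimensions q quantifies the
degree of causal emergence Delta-J = J(f_q) - J(f_p).
"""

from __future__ import annotations

import warnings
from dataclasses import asdict, dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._autodiff import Tensor
from ._nn import Adam
from .coarse_grainer import EncoderSpec, InvertibleEncoder
from .dynamics import DynamicsPair, predict_micro, rollout
from .ei_measures import CEReport, ei_continuous_mc
from .reweighting import compute_weights

__all__ = ["TrainConfig", "NISPlus", "train", "nisplus_loss",
           "normalized_mae", "quantify_ce", "scan_q"]

_LN2 = np.log(2.0)
_SIGMA_FLOOR = 1e-6


@dataclass
class TrainConfig:
    """Hyperparameters of one NIS+ run (see NISPlus for semantics)."""

    q: int = 2
    lam: float = 1.0
    epochs: int = 50
    batch_size: int = 256
    learning_rate: float = 1e-3
    seed: int = 0
    reweight_every: int = 5
    warmup_epochs: int = 10
    error_threshold: float = 0.3
    ei_mc_samples: int = 500
    range_L: float | str = "auto"
    n_coupling_layers: int = 3
    hidden_width: int = 32
    dyn_hidden: int = 32
    clip_max: float = 20.0
    bandwidth: float | str = "auto"
    val_fraction: float = 0.15
    lr_decay: float = 0.01

    def __post_init__(self):
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.error_threshold <= 0:
            raise ValueError("error_threshold must be positive")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


def _as_traj_list(X) -> list[np.ndarray]:
    """Normalize input to a list of (T_i, p) float arrays."""
    if isinstance(X, (list, tuple)):
        trajs = [np.asarray(t, dtype=np.float64) for t in X]
    else:
        X = np.asarray(X, dtype=np.float64)
        trajs = [t for t in X] if X.ndim == 3 else [X]
    if not trajs:
        raise ValueError("empty dataset")
    p = trajs[0].shape[1]
    for t in trajs:
        if t.ndim != 2 or t.shape[1] != p:
            raise ValueError("all trajectories must be (T, p) with equal p")
        if t.shape[0] < 2:
            raise ValueError("each trajectory needs at least two time steps")
        if not np.all(np.isfinite(t)):
            raise ValueError("trajectory contains non-finite values")
    return trajs


def _pairs(trajs: list[np.ndarray]):
    x_t = np.concatenate([t[:-1] for t in trajs])
    x_n = np.concatenate([t[1:] for t in trajs])
    return x_t, x_n


def normalized_mae(pred: np.ndarray, truth: np.ndarray) -> float:
    """MAE scaled by the mean absolute deviation of the truth.

    The denominator is the mean |truth - per-dimension mean of truth|, so a
    predictor that always outputs the truth's mean scores exactly 1 and the
    statistic is invariant to a common rescaling of both arrays.
    """
    pred, truth = np.asarray(pred, float), np.asarray(truth, float)
    if pred.shape != truth.shape:
        raise ValueError("pred and truth shapes differ")
    mae = float(np.mean(np.abs(pred - truth)))
    mad = float(np.mean(np.abs(truth - truth.mean(axis=0))))
    if mad < 1e-12:
        warnings.warn("constant truth: returning unnormalized MAE", RuntimeWarning)
        return mae
    return mae / mad


class NISPlus(BaseEstimator, TransformerMixin):
    """Invertible-encoder macro-dynamics learner maximizing effective information.

    Parameters
    ----------
    q : macro-state dimension (1 <= q <= p).
    lam : Lagrange multiplier on the micro-prediction (reconstruction) term.
    epochs, batch_size, learning_rate : Adam optimization schedule.
    reweight_every : epochs between refreshes of the inverse-probability
        weights (the encoder drifts, so the macro density must be re-estimated).
    warmup_epochs : initial epochs trained on the prediction term only,
        stabilizing the encoder before density estimation starts.
    error_threshold : normalized-MAE level above which a causal-emergence
        verdict is flagged unreliable.
    ei_mc_samples, range_L : Monte-Carlo settings for the per-epoch EI
        estimate; "auto" takes the largest half-width of the observed
        macro-state bounding box.
    seed : single source of randomness (init, batching, decode noise, EI).

    Attributes (after fit)
    ----------
    encoder_ : InvertibleEncoder, dynamics_ : DynamicsPair,
    history_ : per-epoch dicts (forward_loss, inverse_loss, j_bits),
    sigma_ : per-dimension macro residual scales, range_L_ : EI box half-width,
    j_ : final dimension-averaged EI in bits, diverged_ : early-stop flag.
    """

    def __init__(self, q=2, lam=1.0, epochs=50, batch_size=256,
                 learning_rate=1e-3, seed=0, reweight_every=5,
                 warmup_epochs=10, error_threshold=0.3, ei_mc_samples=500,
                 range_L="auto", n_coupling_layers=3, hidden_width=32,
                 dyn_hidden=32, clip_max=20.0, bandwidth="auto",
                 val_fraction=0.15, lr_decay=0.01, verbose=False):
        self.q = q
        self.lam = lam
        self.epochs = epochs
        self.batch_size = batch_size
        self.learning_rate = learning_rate
        self.seed = seed
        self.reweight_every = reweight_every
        self.warmup_epochs = warmup_epochs
        self.error_threshold = error_threshold
        self.ei_mc_samples = ei_mc_samples
        self.range_L = range_L
        self.n_coupling_layers = n_coupling_layers
        self.hidden_width = hidden_width
        self.dyn_hidden = dyn_hidden
        self.clip_max = clip_max
        self.bandwidth = bandwidth
        self.val_fraction = val_fraction
        self.lr_decay = lr_decay
        self.verbose = verbose

    # ------------------------------------------------------------------
    def _loss_terms(self, xb, xnb, wb, rng):
        """Build the loss graph on one batch; returns (fwd, inv) Tensors."""
        enc, dyn = self.encoder_, self.dynamics_
        q, p = enc.q, enc.p
        cols = np.arange(q)
        xt, xn = Tensor(xb), Tensor(xnb)
        y_t = enc.psi(xt).take_columns(cols)
        y_hat = dyn.f(y_t)
        xi = rng.standard_normal((xb.shape[0], p - q)) if q < p else None
        x_hat = enc.decode_t(y_hat, xi)
        fwd = (x_hat - xn).abs().sum(axis=1).mean()
        y_n = enc.psi(xn).take_columns(cols)
        inv = ((y_t - dyn.g(y_n)).abs().sum(axis=1) * Tensor(wb)).mean()
        return fwd, inv

    def _macro_stats(self, x_t_tr, x_val, xn_val):
        """Residual noise scales, EI box half-width from current encoder."""
        enc, dyn = self.encoder_, self.dynamics_
        y_tr = enc.encode(x_t_tr)
        y_v = enc.encode(x_val)
        resid = dyn.f.forward_np(y_v) - enc.encode(xn_val)
        sigma = np.sqrt(np.mean(resid ** 2, axis=0))
        sigma = np.maximum(sigma, _SIGMA_FLOOR)
        if isinstance(self.range_L, str) and self.range_L == "auto":
            # per-dimension half-widths: J is then invariant to linear
            # rescaling of individual macro coordinates
            L = (y_tr.max(axis=0) - y_tr.min(axis=0)) / 2.0
            L = np.maximum(L, 1e-6)
        else:
            L = np.asarray(self.range_L, dtype=np.float64)
        return sigma, L, y_tr

    def fit(self, X, y=None):
        trajs = _as_traj_list(X)
        p = trajs[0].shape[1]
        if not 1 <= self.q <= p:
            raise ValueError(f"q={self.q} outside 1..p={p}")
        self.n_features_in_ = p
        x_t, x_n = _pairs(trajs)
        n = len(x_t)
        rng = np.random.default_rng(self.seed)
        n_val = max(1, int(round(self.val_fraction * n))) if n > 4 else 1
        perm = rng.permutation(n)
        val_idx, tr_idx = perm[:n_val], perm[n_val:]
        if len(tr_idx) == 0:
            tr_idx = perm
        xt_tr, xn_tr = x_t[tr_idx], x_n[tr_idx]
        xt_v, xn_v = x_t[val_idx], x_n[val_idx]

        self.encoder_ = InvertibleEncoder(EncoderSpec(
            p=p, q=self.q, n_coupling_layers=self.n_coupling_layers,
            hidden_width=self.hidden_width, init_seed=self.seed))
        # start the coupling stack from PCA coordinates: the kept (macro)
        # dimensions then already align with the dominant variation
        self.encoder_.fit_prerotation(xt_tr)
        self.dynamics_ = DynamicsPair.create(
            self.q, self.dyn_hidden, np.random.default_rng([self.seed, 1]))
        opt = Adam(self.encoder_.parameters() + self.dynamics_.parameters(),
                   lr=self.learning_rate)
        noise_rng = np.random.default_rng([self.seed, 2])

        n_tr = len(xt_tr)
        weights = np.ones(n_tr)
        self.history_ = []
        self.diverged_ = False
        # exponential learning-rate decay; the L1 losses keep gradient
        # magnitudes O(1) near the optimum, so a fixed step cannot settle
        decay = (self.lr_decay ** (1.0 / max(self.epochs - 1, 1))
                 if self.lr_decay < 1.0 else 1.0)
        for epoch in range(self.epochs):
            opt.lr = self.learning_rate * decay ** epoch
            warmup = epoch < self.warmup_epochs
            if not warmup and (epoch - self.warmup_epochs) % self.reweight_every == 0:
                y_tr = self.encoder_.encode(xt_tr)
                weights = compute_weights(
                    y_tr, bandwidth=self.bandwidth, clip_max=self.clip_max
                ).weights
            order = rng.permutation(n_tr)
            fwd_sum = inv_sum = 0.0
            n_batches = 0
            for lo in range(0, n_tr, self.batch_size):
                idx = order[lo:lo + self.batch_size]
                fwd, inv = self._loss_terms(
                    xt_tr[idx], xn_tr[idx], weights[idx], noise_rng)
                total = fwd * self.lam if warmup else inv + fwd * self.lam
                if not np.isfinite(total.data):
                    self.diverged_ = True
                    break
                opt.zero_grad()
                total.backward()
                opt.step()
                fwd_sum += float(fwd.data)
                inv_sum += float(inv.data)
                n_batches += 1
            if self.diverged_:
                warnings.warn("non-finite loss: stopping early", RuntimeWarning)
                break
            sigma, L, _ = self._macro_stats(xt_tr, xt_v, xn_v)
            est = ei_continuous_mc(
                self.dynamics_.f, sigma, L, mc_samples=self.ei_mc_samples,
                seed=[self.seed, 3, epoch])
            self.sigma_, self.range_L_ = sigma, L
            rec = {
                "epoch": epoch,
                "forward_loss": fwd_sum / max(n_batches, 1),
                "inverse_loss": inv_sum / max(n_batches, 1),
                "j_bits": est.j_dim_avg / _LN2,
            }
            self.history_.append(rec)
            if self.verbose:
                print(f"epoch {epoch:3d}  fwd {rec['forward_loss']:.4f}  "
                      f"inv {rec['inverse_loss']:.4f}  J {rec['j_bits']:.3f}")
        self.j_ = self.history_[-1]["j_bits"] if self.history_ else float("nan")
        return self

    # -- inference -------------------------------------------------------
    def _check_fitted(self):
        if not hasattr(self, "encoder_"):
            raise RuntimeError("estimator is not fitted")

    def transform(self, X) -> np.ndarray:
        """Coarse-grain micro-states to macro-states, phi(x)."""
        self._check_fitted()
        return self.encoder_.encode(np.asarray(X, dtype=np.float64))

    def inverse_transform(self, Y, noise_seed: int = 0) -> np.ndarray:
        self._check_fitted()
        return self.encoder_.decode(np.asarray(Y, dtype=np.float64),
                                    noise_seed=noise_seed)

    def predict(self, X, noise_seed: int = 0) -> np.ndarray:
        """One-step micro prediction for each row of X."""
        self._check_fitted()
        X = np.asarray(X, dtype=np.float64)
        single = X.ndim == 1
        out = predict_micro(self, np.atleast_2d(X), noise_seed=noise_seed)
        return out[0] if single else out

    def rollout(self, x_0, steps: int, noise_seed: int = 0):
        self._check_fitted()
        return rollout(self, x_0, steps, noise_seed=noise_seed)

    def effective_information(self, mc_samples=None, seed=0):
        """EI estimate of the learned macro-dynamics at the fitted noise scales."""
        self._check_fitted()
        return ei_continuous_mc(
            self.dynamics_.f, self.sigma_, self.range_L_,
            mc_samples=mc_samples or self.ei_mc_samples, seed=seed)

    def score(self, X, y=None) -> float:
        """Negative one-step normalized MAE (higher is better)."""
        trajs = _as_traj_list(X)
        x_t, x_n = _pairs(trajs)
        return -normalized_mae(self.predict(x_t), x_n)


def train(dataset, cfg: TrainConfig) -> NISPlus:
    """Fit a NISPlus model from a TrainConfig (functional wrapper)."""
    model = NISPlus(**asdict(cfg))
    return model.fit(dataset)


def nisplus_loss(model: NISPlus, batch, weights=None, noise_seed: int = 0):
    """Evaluate (total, forward_term, inverse_term) of the objective on a batch.

    `batch` is a pair (x_t, x_{t+1}) of aligned (B, p) arrays.
    """
    x_t, x_n = (np.atleast_2d(np.asarray(a, dtype=np.float64)) for a in batch)
    if x_t.shape != x_n.shape:
        raise ValueError("batch arrays must be aligned")
    w = np.ones(len(x_t)) if weights is None else np.asarray(weights, float)
    if len(w) != len(x_t):
        raise ValueError("weights not aligned with batch")
    rng = np.random.default_rng(noise_seed)
    fwd, inv = model._loss_terms(x_t, x_n, w, rng)
    total = float(inv.data) + model.lam * float(fwd.data)
    if not np.isfinite(total):
        raise FloatingPointError(
            f"NaN loss (forward={float(fwd.data)}, inverse={float(inv.data)})")
    return total, float(fwd.data), float(inv.data)


# ----------------------------------------------------------------------
# Causal-emergence quantification across scales
# ----------------------------------------------------------------------

def _multi_step_nmae(model: NISPlus, eval_trajs, steps: int = 10,
                     noise_seed: int = 0) -> float:
    preds, truths = [], []
    for traj in eval_trajs:
        k = min(steps, len(traj) - 1)
        if k < 1:
            continue
        res = model.rollout(traj[0], k, noise_seed=noise_seed)
        m = len(res.states)
        if m == 0:
            return float("inf")
        preds.append(res.states)
        truths.append(traj[1:1 + m])
    if not preds:
        raise ValueError("no trajectory long enough for multi-step evaluation")
    return normalized_mae(np.concatenate(preds), np.concatenate(truths))


def _split_trajs(trajs, seed):
    if len(trajs) < 2:
        return trajs, trajs
    rng = np.random.default_rng([seed, 11])
    order = rng.permutation(len(trajs))
    n_eval = max(1, int(round(0.2 * len(trajs))))
    eval_ids = set(order[:n_eval].tolist())
    train = [t for i, t in enumerate(trajs) if i not in eval_ids]
    held = [t for i, t in enumerate(trajs) if i in eval_ids]
    return train, held


def _fit_scale(dataset_train, q, cfg: TrainConfig) -> NISPlus:
    params = asdict(cfg)
    params["q"] = q
    return NISPlus(**params).fit(dataset_train)


def quantify_ce(dataset, q: int, cfg: TrainConfig | None = None,
                steps: int = 10, return_models: bool = False,
                _micro_model: NISPlus | None = None):
    """Train macro (dimension q) and micro (q = p) models; report Delta-J.

    Delta-J = J(f_q) - J(f_p) in bits per dimension; the report is valid
    only when the macro model's `steps`-step normalized MAE stays at or
    below the error threshold.  With return_models=True the fitted
    (macro, micro) models are returned alongside the CEReport.
    """
    cfg = cfg or TrainConfig()
    trajs = _as_traj_list(dataset)
    p = trajs[0].shape[1]
    if not 1 <= q <= p:
        raise ValueError(f"q={q} outside 1..p={p}")
    n_pairs = sum(len(t) - 1 for t in trajs)
    if n_pairs < 10:
        raise ValueError(
            f"insufficient data: {n_pairs} transition pairs, need >= 10")
    tr, held = _split_trajs(trajs, cfg.seed)
    macro = _fit_scale(tr, q, cfg)
    if q == p:
        micro = macro
    elif _micro_model is not None:
        micro = _micro_model
    else:
        micro = _fit_scale(tr, p, cfg)
    j_q, j_p = macro.j_, micro.j_
    nmae = _multi_step_nmae(macro, held, steps=steps, noise_seed=cfg.seed)
    report = CEReport(
        q=q, j_macro=j_q, j_micro=j_p, delta_j=j_q - j_p, nmae=nmae,
        valid=bool(nmae <= cfg.error_threshold), threshold=cfg.error_threshold)
    if return_models:
        return report, macro, micro
    return report


def scan_q(dataset, q_list, cfg: TrainConfig | None = None,
           steps: int = 10) -> list[CEReport]:
    """quantify_ce at each q in q_list (micro model trained once, shared)."""
    cfg = cfg or TrainConfig()
    trajs = _as_traj_list(dataset)
    p = trajs[0].shape[1]
    if any(not 1 <= q <= p for q in q_list):
        raise ValueError("every q must lie in 1..p")
    if sum(len(t) - 1 for t in trajs) < 10:
        raise ValueError("insufficient data: need >= 10 transition pairs")
    tr, _ = _split_trajs(trajs, cfg.seed)
    micro = _fit_scale(tr, p, cfg) if any(q != p for q in q_list) else None
    return [quantify_ce(dataset, q, cfg, steps=steps, _micro_model=micro)
            for q in q_list]
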