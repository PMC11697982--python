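"""Benchmark micro-data generators.

Three families of synthetic systems exercise the framework:

* a noisy SIR epidemic whose two-dimensional (S, I) state is duplicated
  and observed through Gaussian noise, giving a 4-dimensional micro-state
  with two true degrees of freedom;
* a two-group boids flock (Reynolds rules plus opposite constant turning
  forces per group), with intrinsic heading noise and extrinsic
  observation noise kept separate;
* a stable random linear system embedded by coordinate duplication, used
  as a fixture with a known optimal macro dimension.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SIRConfig", "BoidsConfig", "SIRResult", "BoidsResult",
    "sir_field", "simulate_sir", "simulate_boids", "duplicated_linear_system",
]


# ----------------------------------------------------------------------
# SIR epidemic
# ----------------------------------------------------------------------

@dataclass
class SIRConfig:
    """Noisy SIR micro-data generator settings.

    beta/gamma are the infection and recovery rates; sigma is the standard
    deviation of the isotropic Gaussian observation noise added to the
    duplicated (S, S, I, I) state; region "partial" restricts initial
    conditions to S0 > 1/3.
    """

    beta: float = 1.0
    gamma: float = 0.5
    dt: float = 0.01
    sigma: float = 1e-3
    n_traj: int = 10
    T: int = 100
    region: str = "full"
    seed: int = 0

    def __post_init__(self):
        if min(self.beta, self.gamma, self.dt) <= 0:
            raise ValueError("beta, gamma, dt must be positive")
        if self.sigma < 0:
            raise ValueError("sigma must be non-negative")
        if self.region not in ("full", "partial"):
            raise ValueError(f"unknown region {self.region!r}")


@dataclass
class SIRResult:
    """micro: (n_traj, T, 4) noisy observations; latent: (n_traj, T, 2) = (S, I)."""

    micro: np.ndarray
    latent: np.ndarray
    config: SIRConfig


def sir_field(s: float, i: float, beta: float = 1.0, gamma: float = 0.5):
    """Time derivatives (dS/dt, dI/dt); R follows from R = 1 - S - I."""
    s_arr, i_arr = np.asarray(s, dtype=float), np.asarray(i, dtype=float)
    if np.any(s_arr < -1e-12) or np.any(i_arr < -1e-12) or np.any(s_arr + i_arr > 1 + 1e-9):
        raise ValueError("state must satisfy S, I >= 0 and S + I <= 1")
    return -beta * s_arr * i_arr, beta * s_arr * i_arr - gamma * i_arr


def _rk4_sir(s, i, beta, gamma, dt):
    def f(state):
        s_, i_ = state
        return np.array([-beta * s_ * i_, beta * s_ * i_ - gamma * i_])

    y = np.array([s, i])
    k1 = f(y)
    k2 = f(y + 0.5 * dt * k1)
    k3 = f(y + 0.5 * dt * k2)
    k4 = f(y + dt * k3)
    return y + dt / 6.0 * (k1 + 2 * k2 + 2 * k3 + k4)


def _sample_triangle(rng: np.random.Generator, region: str):
    while True:
        u, v = rng.random(2)
        if u + v > 1:
            u, v = 1 - u, 1 - v
        if region == "partial" and u <= 1 / 3:
            continue
        return u, v


def simulate_sir(cfg: SIRConfig) -> SIRResult:
    """Integrate the SIR dynamics (RK4) and observe it through noise.

    Each trajectory starts from a uniform point of the simplex triangle
    {S, I >= 0, S + I <= 1}; the micro-state at each step is
    (S, S, I, I) + N(0, sigma^2 I_4).
    """
    rng = np.random.default_rng(cfg.seed)
    micro = np.empty((cfg.n_traj, cfg.T, 4))
    latent = np.empty((cfg.n_traj, cfg.T, 2))
    for k in range(cfg.n_traj):
        s, i = _sample_triangle(rng, cfg.region)
        for t in range(cfg.T):
            latent[k, t] = (s, i)
            xi = rng.standard_normal(4) * cfg.sigma
            micro[k, t] = np.array([s, s, i, i]) + xi
            s, i = _rk4_sir(s, i, cfg.beta, cfg.gamma, cfg.dt)
    return SIRResult(micro=micro, latent=latent, config=cfg)


# ----------------------------------------------------------------------
# Boids flocking
# ----------------------------------------------------------------------

@dataclass
class BoidsConfig:
    """Two-group Reynolds boids with per-group constant turning forces.

    alpha scales an intrinsic per-boid, per-step heading perturbation
    uniform on alpha*[-pi, pi]; delta_max is the standard deviation of the
    extrinsic observation noise added to the recorded micro-states only.
    """

    n_boids: int = 16
    canvas: float = 300.0
    group_turn_forces: tuple = (0.05, -0.05)  # radians per step
    alpha: float = 0.0
    delta_max: float = 0.0
    T: int = 100
    seed: int = 0
    speed: float = 3.0
    cohesion_radius: float = 60.0
    alignment_radius: float = 60.0
    separation_radius: float = 10.0
    cohesion_weight: float = 0.01
    alignment_weight: float = 0.12
    separation_weight: float = 0.15
    init_radius: float = 30.0

    def __post_init__(self):
        if self.n_boids < 1:
            raise ValueError("n_boids must be >= 1")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")
        if self.delta_max < 0:
            raise ValueError("delta_max must be non-negative")


@dataclass
class BoidsResult:
    """clean/observed: (T, 4 n_boids) with per-boid layout (x, y, vx, vy)."""

    clean: np.ndarray
    observed: np.ndarray
    groups: np.ndarray
    config: BoidsConfig


def _rotate(v: np.ndarray, angle) -> np.ndarray:
    c, s = np.cos(angle), np.sin(angle)
    return np.stack([c * v[:, 0] - s * v[:, 1], s * v[:, 0] + c * v[:, 1]], axis=1)


def simulate_boids(cfg: BoidsConfig) -> BoidsResult:
    """Simulate the flock and return clean plus noise-observed micro-series.

    Reynolds rules (cohesion, alignment, separation) act between boids of
    the same group within per-rule radii; each group additionally turns by
    its constant force every step.  Speed is held constant, positions wrap
    on the canvas torus.  Extrinsic noise perturbs observations only: the
    clean series is the actual system state.
    """
    n, rng = cfg.n_boids, np.random.default_rng(cfg.seed)
    groups = np.arange(n) * len(cfg.group_turn_forces) // max(n, 1)
    groups = np.minimum(groups, len(cfg.group_turn_forces) - 1)
    center = cfg.canvas / 2.0
    r = cfg.init_radius * np.sqrt(rng.random(n))
    theta = rng.uniform(0, 2 * np.pi, n)
    pos = center + np.stack([r * np.cos(theta), r * np.sin(theta)], axis=1)
    heading = rng.uniform(0, 2 * np.pi, n)
    vel = cfg.speed * np.stack([np.cos(heading), np.sin(heading)], axis=1)

    clean = np.empty((cfg.T, 4 * n))
    for t in range(cfg.T):
        clean[t] = np.concatenate(
            [np.concatenate([pos[i], vel[i]]) for i in range(n)]
        )
        steer = np.zeros((n, 2))
        for i in range(n):
            same = np.flatnonzero((groups == groups[i]) & (np.arange(n) != i))
            if same.size:
                d = pos[same] - pos[i]
                dist = np.hypot(d[:, 0], d[:, 1])
                coh = dist < cfg.cohesion_radius
                if coh.any():
                    steer[i] += cfg.cohesion_weight * (
                        pos[same][coh].mean(axis=0) - pos[i]
                    )
                ali = dist < cfg.alignment_radius
                if ali.any():
                    steer[i] += cfg.alignment_weight * (
                        vel[same][ali].mean(axis=0) - vel[i]
                    )
                sep = dist < cfg.separation_radius
                if sep.any():
                    steer[i] -= cfg.separation_weight * d[sep].sum(axis=0)
        vel = vel + steer
        turn = np.array([cfg.group_turn_forces[g] for g in groups])
        if cfg.alpha > 0:
            turn = turn + rng.uniform(-cfg.alpha * np.pi, cfg.alpha * np.pi, n)
        vel = _rotate(vel, turn)
        norm = np.hypot(vel[:, 0], vel[:, 1])
        vel = cfg.speed * vel / norm[:, None]
        pos = np.mod(pos + vel, cfg.canvas)

    if cfg.delta_max > 0:
        observed = clean + rng.normal(0.0, cfg.delta_max, size=clean.shape)
    else:
        observed = clean.copy()
    return BoidsResult(clean=clean, observed=observed, groups=groups, config=cfg)


# ----------------------------------------------------------------------
# Duplicated linear fixture
# ----------------------------------------------------------------------

def duplicated_linear_system(dim_true: int, dim_obs: int, noise: float,
                             T: int, seed: int = 0,
                             n_traj: int = 1) -> np.ndarray:
    """Stable random linear dynamics embedded by coordinate duplication.

    z_{t+1} = A z_t with a random A redrawn until its spectral radius is
    below 1 (then nudged toward 0.95 for persistent signal); observations
    are x_t[j] = z_t[j mod dim_true] + N(0, noise^2).  Returns (T, dim_obs)
    or (n_traj, T, dim_obs) when n_traj > 1.
    """
    if dim_true > dim_obs:
        raise ValueError("dim_true must not exceed dim_obs")
    rng = np.random.default_rng(seed)
    while True:
        A = rng.normal(0, 1.0 / np.sqrt(dim_true), size=(dim_true, dim_true))
        rho = np.max(np.abs(np.linalg.eigvals(A)))
        if rho < 1:
            break
    A *= 0.95 / max(rho, 1e-6)
    dup = np.arange(dim_obs) % dim_true
    out = np.empty((n_traj, T, dim_obs))
    for k in range(n_traj):
        z = rng.standard_normal(dim_true)
        for t in range(T):
            x = z[dup]
            if noise > 0:
                x = x + rng.normal(0, noise, size=dim_obs)
            out[k, t] = x
            z = A @ z
    return out[0] if n_traj == 1 else out
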