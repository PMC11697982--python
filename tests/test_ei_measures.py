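"""Effective-information measures against exact and numerical oracles."""

import numpy as np
import pytest
from scipy.stats import norm

from nisplus import (Partition, TransitionMatrix, coarse_grain_tpm, delta_j,
                     ei_continuous_mc, ei_discrete, psi_indicator)

LN2PIE = np.log(2 * np.pi * np.e)


def eight_state_chain():
    """Absorbing-plus-uniform chain: states 0-6 uniform among 0-6, state 7 fixed."""
    P = np.zeros((8, 8))
    P[:7, :7] = 1.0 / 7.0
    P[7, 7] = 1.0
    return P


def brute_force_ei(P, base=2.0):
    """MI of the explicit joint p(x, y) = P[x, y] / n (independent oracle)."""
    n = P.shape[0]
    joint = P / n
    px = joint.sum(axis=1, keepdims=True)
    py = joint.sum(axis=0, keepdims=True)
    mask = joint > 0
    return float((joint[mask]
                  * np.log(joint[mask] / (px @ py)[mask])).sum() / np.log(base))


# ----------------------------------------------------------------------
# discrete EI
# ----------------------------------------------------------------------

def test_two_state_identity_is_one_bit():
    assert ei_discrete(np.eye(2), log_base=2) == pytest.approx(1.0, abs=1e-12)


def test_eight_state_chain_closed_form():
    expected = 3.0 - (7.0 / 8.0) * np.log2(7.0)
    assert ei_discrete(eight_state_chain()) == pytest.approx(expected, abs=1e-12)


def test_identical_rows_have_zero_ei(rng):
    row = rng.dirichlet(np.ones(5))
    P = np.tile(row, (5, 1))
    assert ei_discrete(P) == pytest.approx(0.0, abs=1e-12)


def test_ei_equals_brute_force_mi_on_random_matrices(rng):
    for _ in range(100):
        n = int(rng.integers(1, 9))
        P = rng.dirichlet(np.ones(n), size=n)
        assert ei_discrete(P) == pytest.approx(brute_force_ei(P), abs=1e-10)


def test_permutation_matrix_maximizes_ei(rng):
    for n in (2, 4, 7):
        P = np.eye(n)[rng.permutation(n)]
        assert ei_discrete(P) == pytest.approx(np.log2(n), abs=1e-12)
    # non-permutation stays strictly below log2(n)
    P = rng.dirichlet(np.ones(4), size=4)
    assert ei_discrete(P) < np.log2(4)


def test_discrete_ei_input_validation():
    with pytest.raises(ValueError, match="row 1"):
        ei_discrete(np.array([[1.0, 0.0], [0.4, 0.7]]))
    with pytest.raises(ValueError):
        ei_discrete(np.eye(2), log_base=1.0)
    with pytest.raises(ValueError):
        ei_discrete(np.eye(2), log_base=-2.0)


# ----------------------------------------------------------------------
# coarse graining
# ----------------------------------------------------------------------

def test_chain_coarse_grains_to_identity():
    macro = coarse_grain_tpm(eight_state_chain(),
                             Partition([list(range(7)), [7]]))
    assert np.allclose(macro.probs, np.eye(2))
    assert ei_discrete(macro) == pytest.approx(1.0, abs=1e-12)


def test_singleton_partition_is_identity_coarse_graining(rng):
    P = rng.dirichlet(np.ones(4), size=4)
    macro = coarse_grain_tpm(P, Partition([[i] for i in range(4)]))
    assert np.allclose(macro.probs, P)


def test_total_aggregation_gives_trivial_chain(rng):
    P = rng.dirichlet(np.ones(5), size=5)
    macro = coarse_grain_tpm(P, Partition([list(range(5))]))
    assert np.allclose(macro.probs, [[1.0]])


def test_coarse_grained_matrix_is_row_stochastic(rng):
    P = rng.dirichlet(np.ones(6), size=6)
    macro = coarse_grain_tpm(P, Partition([[0, 3], [1, 2], [4, 5]]))
    assert np.allclose(macro.probs.sum(axis=1), 1.0, atol=1e-12)


def test_invalid_partitions_rejected():
    P = np.eye(3)
    with pytest.raises(ValueError, match="overlap"):
        coarse_grain_tpm(P, Partition([[0, 1], [1, 2]]))
    with pytest.raises(ValueError, match="cover"):
        coarse_grain_tpm(P, Partition([[0], [2]]))
    with pytest.raises(ValueError, match="empty"):
        Partition([[0, 1, 2], []])


# ----------------------------------------------------------------------
# continuous EI
# ----------------------------------------------------------------------

def linear_channel_closed_form(A, sigmas, L):
    q = len(sigmas)
    return (np.log(np.abs(np.linalg.det(A))) + q * np.log(2 * L)
            - 0.5 * q * LN2PIE - np.log(sigmas).sum())


def test_linear_channels_match_closed_form(rng):
    for _ in range(6):
        q = int(rng.integers(1, 4))
        A = rng.normal(0, 1, (q, q)) + np.eye(q)
        sig = rng.uniform(0.05, 0.5, q)
        L = float(rng.uniform(0.5, 3.0))
        est = ei_continuous_mc(lambda y, A=A: y @ A.T, sig, L,
                               mc_samples=200, seed=3)
        closed = linear_channel_closed_form(A, sig, L)
        tol = max(3 * est.mc_stderr, 1e-8)
        assert abs(est.ei_total - closed) <= tol
        assert est.j_dim_avg * q == pytest.approx(est.ei_total, abs=1e-12)


def test_identity_map_has_zero_mc_variance():
    q, sig, L = 3, 0.2, 1.5
    est = ei_continuous_mc(lambda y: y, np.full(q, sig), L,
                           mc_samples=64, seed=0)
    expected = q * np.log(2 * L) - 0.5 * q * LN2PIE - q * np.log(sig)
    assert est.ei_total == pytest.approx(expected, abs=1e-10)
    assert est.mc_stderr == pytest.approx(0.0, abs=1e-10)


def test_rotation_is_volume_preserving(rng):
    theta = float(rng.uniform(0, 2 * np.pi))
    R = np.array([[np.cos(theta), -np.sin(theta)],
                  [np.sin(theta), np.cos(theta)]])
    sig = rng.uniform(0.05, 0.4, 2)
    est_rot = ei_continuous_mc(lambda y: y @ R.T, sig, 2.0, 128, seed=5)
    est_id = ei_continuous_mc(lambda y: y, sig, 2.0, 128, seed=5)
    assert est_rot.ei_total == pytest.approx(est_id.ei_total, abs=1e-8)


def test_formula_tracks_numerically_integrated_mi():
    """For y = 2x + eps, the EI formula approximates the true channel MI.

    Oracle: high-resolution integration of h(Y) for the uniform-input
    Gaussian channel; the formula neglects edge smoothing, an O(sigma/L)
    effect, so agreement is to a few percent at sigma/L = 0.1.
    """
    sig, a = 0.1, 2.0  # output range [-2a.., slope 2, L=1
    ys = np.linspace(-a - 6 * sig, a + 6 * sig, 100001)
    p = (norm.cdf((ys + a) / sig) - norm.cdf((ys - a) / sig)) / (2 * a)
    p = np.clip(p, 1e-300, None)
    h_y = -np.trapezoid(p * np.log(p), ys)
    mi_true = h_y - 0.5 * np.log(2 * np.pi * np.e * sig ** 2)
    est = ei_continuous_mc(lambda y: 2 * y, [sig], 1.0, 256, seed=0)
    assert est.ei_total == pytest.approx(mi_true, rel=0.05)


def test_per_dimension_intervention_box(rng):
    sig = np.array([0.1, 0.2])
    est = ei_continuous_mc(lambda y: y, sig, [0.5, 2.0], 64, seed=0)
    expected = (np.log(2 * 0.5) + np.log(2 * 2.0) - LN2PIE - np.log(sig).sum())
    assert est.ei_total == pytest.approx(expected, abs=1e-10)


def test_degenerate_map_is_finite():
    est = ei_continuous_mc(lambda y: 0.0 * y, [0.1, 0.1], 1.0, 32, seed=0)
    assert np.isfinite(est.ei_total)
    assert est.ei_total < -20  # singular-value floor pushes EI far negative


def test_continuous_ei_parameter_validation():
    with pytest.raises(ValueError):
        ei_continuous_mc(lambda y: y, [0.1], 1.0, mc_samples=0)
    with pytest.raises(ValueError):
        ei_continuous_mc(lambda y: y, [-0.1], 1.0)
    with pytest.raises(ValueError):
        ei_continuous_mc(lambda y: y, [0.1], -1.0)


# ----------------------------------------------------------------------
# Delta-J and Psi
# ----------------------------------------------------------------------

def test_delta_j_values_and_antisymmetry(rng):
    assert delta_j(1.0, 0.55) == pytest.approx(0.45)
    assert delta_j(0.2, 0.7) == pytest.approx(-0.5)
    for _ in range(20):
        a, b = rng.normal(0, 5, 2)
        assert delta_j(a, a) == 0.0
        assert delta_j(a, b) == -delta_j(b, a)
    with pytest.raises(ValueError):
        delta_j(np.nan, 1.0)


def _parity_chain(T, seed, flip=0.1):
    """x in {0,1}^2; next state uniform among states of the same parity,
    except that parity flips with probability `flip` (mixing the chain)."""
    rng = np.random.default_rng(seed)
    states = np.array([[0, 0], [0, 1], [1, 0], [1, 1]])
    parity = states.sum(axis=1) % 2
    idx = rng.integers(0, 4)
    out = np.empty((T, 2), dtype=int)
    for t in range(T):
        out[t] = states[idx]
        target = parity[idx] ^ (rng.random() < flip)
        idx = rng.choice(np.flatnonzero(parity == target))
    return out, out.sum(axis=1) % 2


def _parity_psi_oracle(flip):
    """Exhaustive enumeration of the 4-state joint distribution.

    The single-bit micro terms vanish exactly (each bit is independent of
    the next parity under the uniform stationary law), so Psi equals the
    macro self-MI, 1 - H2(flip); the parity macro carries one full bit of
    synergistic information in the deterministic limit flip -> 0.
    """
    h2 = -flip * np.log2(flip) - (1 - flip) * np.log2(1 - flip) if 0 < flip < 1 else 0.0
    return 1.0 - h2


@pytest.mark.parametrize("flip", [0.1, 0.5])
def test_psi_parity_toy_matches_enumeration_oracle(flip):
    micro, V = _parity_chain(30000, seed=0, flip=flip)
    psi = psi_indicator(micro, V, mi_estimator="discrete")
    assert psi == pytest.approx(_parity_psi_oracle(flip), abs=0.05)


def test_psi_parity_approaches_one_bit_in_deterministic_limit():
    micro, V = _parity_chain(30000, seed=2, flip=0.005)
    psi = psi_indicator(micro, V, mi_estimator="discrete")
    assert psi == pytest.approx(_parity_psi_oracle(0.005), abs=0.05)
    assert psi > 0.9  # essentially the full one-bit synergy


def test_psi_invariant_to_micro_dimension_order():
    micro, V = _parity_chain(2000, seed=1)
    a = psi_indicator(micro, V, mi_estimator="discrete")
    b = psi_indicator(micro[:, ::-1], V, mi_estimator="discrete")
    assert a == pytest.approx(b, abs=1e-12)


def test_psi_copy_chain_cancels_to_zero(rng):
    """V = b1 where b1 is a sticky bit and b2 is iid noise.

    The macro's own MI, I(V_t; V_{t+1}), equals the single informative
    micro term I(b1_t; V_{t+1}) exactly, and b2 contributes nothing, so
    the indicator cancels to zero (no synergy in a copy chain).
    """
    T = 4000
    b1 = np.empty(T, dtype=int)
    b1[0] = rng.integers(0, 2)
    flips = rng.random(T - 1) < 0.1
    for t in range(1, T):
        b1[t] = b1[t - 1] ^ flips[t - 1]
    micro = np.stack([b1, rng.integers(0, 2, T)], axis=1)
    psi = psi_indicator(micro, b1, mi_estimator="discrete")
    assert psi == pytest.approx(0.0, abs=0.05)


def test_psi_constant_macro_warns_and_returns_zero(rng):
    micro = rng.normal(0, 1, (100, 3))
    with pytest.warns(RuntimeWarning):
        assert psi_indicator(micro, np.ones(100), mi_estimator="gaussian") == 0.0


def test_psi_input_validation(rng):
    with pytest.raises(ValueError):
        psi_indicator(rng.normal(0, 1, (10, 2)), np.zeros(9))
    with pytest.raises(ValueError):
        psi_indicator(rng.normal(0, 1, (1, 2)), np.zeros(1))
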