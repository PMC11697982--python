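"""Shared fixtures: simulated data and trained models reused across tests.

The SIR training is the expensive part of the suite, so one macro/micro
model pair (q = 2 vs q = p = 4) is fitted once per session and shared by
the causal-emergence, vector-field and property tests.
"""

import numpy as np
import pytest

from nisplus import SIRConfig, TrainConfig, quantify_ce, simulate_sir

SIR_TRAIN_CFG = TrainConfig(
    q=2, epochs=120, learning_rate=2e-3, batch_size=256, seed=0,
    warmup_epochs=10, ei_mc_samples=400,
)


@pytest.fixture()
def rng():
    # fresh, fixed-seed generator per test: draws do not depend on which
    # subset of the suite runs
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def sir_data():
    """Noisy SIR micro-data at low observational noise (sigma = 1e-3)."""
    return simulate_sir(SIRConfig(sigma=1e-3, n_traj=60, T=80, seed=0))


@pytest.fixture(scope="session")
def sir_ce(sir_data):
    """(CEReport, macro q=2 model, micro q=4 model) on the SIR data."""
    report, macro, micro = quantify_ce(
        list(sir_data.micro), 2, SIR_TRAIN_CFG, return_models=True)
    return report, macro, micro
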