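"""Shared fixtures: random stable systems and synthetic suites."""

import numpy as np
import pytest

from dsfnet.circuits import ExperimentSuite, Trajectory
from dsfnet.dsf_core import PartitionedLTI
from dsfnet.estimation import simulate_discrete


def random_stable_partitioned(rng, n_max=8, p_max=4, m_max=4):
    """A random Hurwitz partitioned LTI with measured-first ordering."""
    n = rng.integers(2, n_max + 1)
    p = rng.integers(1, min(p_max, n) + 1)
    m = rng.integers(1, m_max + 1)
    A = rng.standard_normal((n, n))
    # shift to stability: subtract a margin beyond the spectral abscissa
    alpha = max(np.real(np.linalg.eigvals(A)).max(), 0.0)
    A -= (alpha + rng.uniform(0.5, 1.5)) * np.eye(n)
    B = rng.standard_normal((n, m))
    return PartitionedLTI.from_full(A, B, int(p))


def step_suite_from_discrete(ddsf, T=160, onsets=(12, 48, 84), amps=None,
                             noise_sd=0.0, rng=None, baseline_n=8):
    """Simulate a known discrete DSF under serial steps into a suite."""
    p = ddsf.p
    amps = amps if amps is not None else 1.0 + 0.5 * np.arange(p)
    U = np.zeros((T, p))
    for i in range(p):
        on = onsets[i % len(onsets)]
        U[on:on + max(T // 4, 10), i] = amps[i]
    Y = simulate_discrete(ddsf, U)
    if noise_sd > 0:
        Y = Y + rng.standard_normal(Y.shape) * noise_sd
    traj = Trajectory(np.arange(T, dtype=float) * ddsf.dt, Y, U,
                      {"baseline_n": baseline_n, "detrended": True})
    return ExperimentSuite([traj], list(ddsf.output_names),
                           list(ddsf.input_names), None)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230915)


@pytest.fixture(scope="session")
def iffl_models():
    from dsfnet.circuits import builtin_model
    return builtin_model("iffl_ideal"), builtin_model("iffl_crosstalk")


@pytest.fixture(scope="session")
def iffl_ops(iffl_models):
    """Equilibria of both feedforward circuits at the reference baseline."""
    from dsfnet.circuits import IFFL_BASELINE_INPUT, find_equilibrium
    mi, mx = iffl_models
    return (find_equilibrium(mi, IFFL_BASELINE_INPUT),
            find_equilibrium(mx, IFFL_BASELINE_INPUT))
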