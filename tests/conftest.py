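"""Shared fixtures: random networks and the reduced end-to-end run.

The full deprivation experiment (reduced M=10, N=40 network) takes a couple
of minutes, so it is run once per session and shared by every test that
inspects its outcome.
"""

from __future__ import annotations

import numpy as np
import pytest

from emnet import (
    NetworkParams,
    deprivation_experiment,
    small_config,
    spectral_radius,
)


def make_random_network(
    seed: int, m: int = 5, n: int = 10, rho: float = 2.0
) -> tuple[NetworkParams, np.ndarray]:
    """Random subcritical network plus a random stimulus in [0, 0.5]."""
    rng = np.random.default_rng(seed)
    W = rng.normal(0.0, 0.7, (n, m))
    K = rng.normal(0.0, 1.0, (n, n))
    np.fill_diagonal(K, 0.0)
    K *= rho / spectral_radius(K)
    T = rng.normal(0.0, 0.3, n)
    x = rng.uniform(0.0, 0.5, m)
    return NetworkParams(W, K, T), x


@pytest.fixture(scope="session")
def small_run():
    """One full deprivation experiment at the reduced network size."""
    return deprivation_experiment(small_config())


@pytest.fixture(scope="session")
def small_cfg():
    return small_config()
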