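"""Shared fixtures: small networks and fast simulation settings."""

from __future__ import annotations

import numpy as np
import pytest

from grncontrol import SimulationSettings, build_network
from grncontrol.examples import mutual_inhibition, toy_network


@pytest.fixture(scope="session")
def fast_settings() -> SimulationSettings:
    """Settings small enough for unit tests, tight enough for exact checks."""
    return SimulationSettings(
        mc_samples=100, seed=7, t_max=120.0, relax_dt=0.5, relax_after=20.0,
        dc_tol=1e-2,
    )


@pytest.fixture(scope="session")
def toy():
    return toy_network()


@pytest.fixture(scope="session")
def toggle():
    return mutual_inhibition()


@pytest.fixture(scope="session")
def chain():
    """A -> B -> C relay chain with a self-loop on A (SQDS)."""
    return build_network(
        ["A", "B", "C"],
        [("A", "A", "+"), ("A", "B", "+"), ("B", "C", "+")],
        interpolation="sqds",
        name="chain",
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
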