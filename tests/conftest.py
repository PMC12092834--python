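"""Shared fixtures: everything is generated programmatically at test time."""

from __future__ import annotations

import numpy as np
import pytest

from mea_sbi import FixedParams, FreeParams, compute_features, simulate_network
from mea_sbi.fixtures import crafted_raster, toy_training_set


@pytest.fixture(scope="session")
def fast_fixed() -> FixedParams:
    """Coarse-step integration settings used throughout the tests."""
    return FixedParams().replace(dt=0.1)


@pytest.fixture(scope="session")
def midprior_sim(fast_fixed):
    """One 60 s reduced-size simulation at mid-prior parameters (cached)."""
    return simulate_network(
        FreeParams(), fixed=fast_fixed, duration=60.0, seed=11, n_neurons=50
    )


@pytest.fixture(scope="session")
def bursty_raster():
    """Crafted raster with 3 equally spaced network bursts on 12 electrodes."""
    return crafted_raster(
        n_bursts=3, period_s=10.0, burst_duration=0.3, duration=60.0,
        background_rate=0.4, seed=5,
    )


@pytest.fixture(scope="session")
def toy_ts():
    """Linear-Gaussian toy training set (n=5000, 1-D)."""
    return toy_training_set(n=5000, d=1, seed=3)
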