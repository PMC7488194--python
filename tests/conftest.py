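"""Shared fixtures.

Expensive artifacts (grown networks) are session-scoped; everything is
generated programmatically from fixed seeds.
"""

from __future__ import annotations

import numpy as np
import pytest

from neuroculture.dynamics import SpikeRaster
from neuroculture.growth import GrowthConfig, grow_network
from neuroculture.substrate import build_pattern


@pytest.fixture(scope="session")
def empty_pattern():
    return build_pattern("empty", 2)


@pytest.fixture(scope="session")
def crosses_pattern():
    return build_pattern("crosses_full", 2)


@pytest.fixture(scope="session")
def small_config():
    # low density keeps module-level tests fast; statistics-grade tests build
    # their own full-density ensembles
    return GrowthConfig(density=60.0, seed=0)


@pytest.fixture(scope="session")
def small_empty_net(empty_pattern, small_config):
    return grow_network(empty_pattern, small_config, seed=11)


@pytest.fixture(scope="session")
def small_crosses_net(crosses_pattern, small_config):
    return grow_network(crosses_pattern, small_config, seed=11)


def make_raster(ids, times, n_neurons, duration) -> SpikeRaster:
    ids = np.asarray(ids, np.int64)
    times = np.asarray(times, float)
    order = np.argsort(times, kind="stable")
    return SpikeRaster(neuron_ids=ids[order], times=times[order],
                       n_neurons=n_neurons, duration=duration)


@pytest.fixture
def synthetic_burst_raster():
    """Three 40%-participation bursts plus Poisson background spikes."""
    rng = np.random.default_rng(5)
    n = 100
    ids, times = [], []
    for t0 in (10.0, 40.0, 70.0):
        chosen = rng.choice(n, size=40, replace=False)
        for c in chosen:
            ids.append(c)
            times.append(t0 + rng.uniform(0, 0.2))
    bg = rng.uniform(0, 100, size=60)
    ids.extend(rng.integers(0, n, size=60).tolist())
    times.extend(bg.tolist())
    return make_raster(ids, times, n, 100.0)
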