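"""Shared fixtures: synthetic worlds with and without observation noise.

Session-scoped because world construction and grid fits are the slow parts;
all tests treat these objects as read-only.
"""

import numpy as np
import pytest

from paleoemu.emulator import fit_grid
from paleoemu.synthetic import make_snapshots, make_world


@pytest.fixture(scope="session")
def world_clean():
    """Noise-free world: fits must recover the truth exactly."""
    return make_world(seed=2, noise_sd=0.0)


@pytest.fixture(scope="session")
def snaps_clean(world_clean):
    return make_snapshots(world_clean, noise=False)


@pytest.fixture(scope="session")
def model_clean(world_clean, snaps_clean):
    return fit_grid(snaps_clean, snaps_clean.epochs, world_clean.forcings,
                    stats=world_clean.stats)


@pytest.fixture(scope="session")
def world_noisy():
    """Default-noise world (regression-scale sd 0.2)."""
    return make_world(seed=7)


@pytest.fixture(scope="session")
def snaps_noisy(world_noisy):
    return make_snapshots(world_noisy, noise=True)


@pytest.fixture(scope="session")
def model_noisy(world_noisy, snaps_noisy):
    return fit_grid(snaps_noisy, snaps_noisy.epochs, world_noisy.forcings,
                    stats=world_noisy.stats)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
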