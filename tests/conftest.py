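"""Shared fixtures: small phantoms and patterns built at test time."""

import numpy as np
import pytest
from hypothesis import settings

from specklekit import simulate

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")
from specklekit.types import DiffractionPattern


@pytest.fixture(scope="session")
def phantom64():
    return simulate.make_phantom(seed=1, grid_size=64, object_fraction=0.08)


@pytest.fixture(scope="session")
def pattern64(phantom64):
    return simulate.diffract(phantom64)


@pytest.fixture(scope="session")
def noisy_pattern64(pattern64):
    pat = simulate.add_poisson_noise(pattern64, photon_budget=1e6, seed=7)
    return simulate.apply_beamstop_and_symmetrize(pat, 3, (1, 2))


@pytest.fixture()
def flat_pattern():
    """Uniform intensity, all valid — handy for closed-form shell statistics."""
    n = 64
    return DiffractionPattern(
        intensity=np.full((n, n), 5.0),
        valid=np.ones((n, n), dtype=bool),
        freq_per_pixel=0.5,
    )
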