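"""Shared fixtures: cheap chains and synthetic frames."""

import numpy as np
import pytest

from shearfold import SimParams
from shearfold.fixtures import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def tiny_params() -> SimParams:
    """A 20-bead chain, cheap enough for dynamical unit tests."""
    return SimParams(n_beads=20, n_replicas=2, n_samples=60, seed=7)


@pytest.fixture()
def rod_pair():
    """Straight 100-bead chain along the flow axis, zero tensions."""
    return generate_fixture(FixtureSpec("rod", n_beads=100))


@pytest.fixture()
def globule_pair():
    """Compact random 100-bead cloud well inside the chain-level LCC radius."""
    return generate_fixture(FixtureSpec("globule", n_beads=100, radius=300.0, seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
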