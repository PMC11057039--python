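import numpy as np
import pytest
from hypothesis import settings

# deterministic property-test examples, independent of any CLI options
settings.register_profile("deterministic", derandomize=True)
settings.load_profile("deterministic")

from crowdiff.core import Configuration, PeriodicBox, PhysicalEnvironment


@pytest.fixture
def env():
    return PhysicalEnvironment(temperature=298.0, solvent_viscosity=0.89)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def single_crowder_config():
    """One 5.1 nm sphere centred in a 40 nm box."""
    return Configuration(
        PeriodicBox(40.0), ["crowder"], np.array([[20.0, 20.0, 20.0]]), np.array([5.1])
    )


@pytest.fixture
def two_species_config():
    """Two well-separated particles of different species."""
    return Configuration(
        PeriodicBox(30.0),
        ["a", "b"],
        np.array([[5.0, 5.0, 5.0], [20.0, 20.0, 20.0]]),
        np.array([2.0, 1.0]),
    )


def brute_force_overlap_pairs(positions, radii, edge, tol=1e-9):
    """Independent O(N²) overlap oracle (minimum image), loop-based."""
    n = len(radii)
    pairs = []
    for i in range(n - 1):
        for j in range(i + 1, n):
            d = positions[j] - positions[i]
            d = d - edge * np.round(d / edge)
            if np.sqrt(np.dot(d, d)) < radii[i] + radii[j] - tol:
                pairs.append((i, j))
    return pairs


@pytest.fixture
def overlap_oracle():
    return brute_force_overlap_pairs
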