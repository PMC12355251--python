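import numpy as np
import pytest

from hingeflex import (
    ToyProteinSpec,
    build_toy_protein,
    simulate_hinge_langevin,
    toy_domain_map,
)


@pytest.fixture(scope="session")
def small_spec():
    """Desk-scale toy protein: 3 domains x 12 beads + 2 hinges x 3 beads."""
    return ToyProteinSpec(beads_per_domain=12, beads_per_hinge=3,
                          domain_blob_radius=6.0, arm_length=25.0)


@pytest.fixture(scope="session")
def small_map(small_spec):
    return toy_domain_map(small_spec)


@pytest.fixture(scope="session")
def open_structure(small_spec):
    return build_toy_protein(small_spec, state="open", seed=1)


@pytest.fixture(scope="session")
def closed_structure(small_spec):
    return build_toy_protein(small_spec, state="closed", seed=1)


@pytest.fixture(scope="session")
def short_traj(small_spec, open_structure):
    return simulate_hinge_langevin(open_structure, small_spec, n_frames=400,
                                   temperature=310.0, seed=7)


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
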