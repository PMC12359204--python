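import numpy as np
import pytest

from lanthimodel.fixtures import DEFAULT_TOPOLOGY_SPEC, FixtureRecipe, make_noe_set, make_two_state_pool
from lanthimodel.sampler import SamplerConfig, SimpleScore, sample_unstructured
from lanthimodel.topology import parse_topology


@pytest.fixture(scope="session")
def topo8():
    """Small single-ring peptide used by fast geometry/sampler tests."""
    return parse_topology("seq AAAAACAA\nring 2-6 lan\n")


@pytest.fixture(scope="session")
def topo15():
    """The default two-ring synthetic lanthipeptide."""
    return parse_topology(DEFAULT_TOPOLOGY_SPEC)


@pytest.fixture(scope="session")
def pool8(topo8):
    """A dozen ring-closed conformers of the small peptide."""
    return sample_unstructured(topo8, SamplerConfig(n_models=12, seed=7))


@pytest.fixture(scope="session")
def simple_score():
    return SimpleScore()


@pytest.fixture(scope="session")
def two_state_fixture():
    """Planted two-state pool with NOE observations from the equal mixture.

    Session-scoped: pool generation closes two thioether rings per model
    and is the most expensive fixture in the suite.
    """
    recipe = FixtureRecipe(seed=11)
    pool, labels = make_two_state_pool(recipe)
    rng = np.random.default_rng(recipe.seed + 1)
    restraints = make_noe_set(pool[:2], recipe.n_restraints,
                              recipe.noise_sd, rng)
    return recipe, pool, labels, restraints
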