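import pytest

from treevigor import JointGrowthMortalityModel, McmcConfig, SimConfig, simulate_census
from treevigor.simulate import reference_params


@pytest.fixture(scope="session")
def ref_params():
    return reference_params()


@pytest.fixture(scope="session")
def small_sim():
    """A small Paracou-like community: 1200 trees, 3 censuses."""
    return simulate_census(SimConfig(n_trees=1200), seed=42)


@pytest.fixture(scope="session")
def small_model(small_sim):
    return JointGrowthMortalityModel(small_sim.census, small_sim.traits)


@pytest.fixture(scope="session")
def short_config():
    """Chain settings scaled down for unit-level integration checks."""
    return McmcConfig(n_chains=1, n_iter_phase1=800, n_iter_phase2=1200,
                      burn_in=400, thinning=5)


@pytest.fixture(scope="session")
def medium_fit(short_config):
    """A 3000-tree community fitted with a short chain (shared across
    integration tests to amortize the sampler cost)."""
    sim = simulate_census(SimConfig(n_trees=3000), seed=11)
    model = JointGrowthMortalityModel(sim.census, sim.traits)
    results = model.fit(short_config, seed=5)
    return sim, model, results
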