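import numpy as np
import pytest

import kisbreed as kb


@pytest.fixture(scope="session")
def small_genome():
    """4 chromosomes x 50 markers, 1 Morgan each."""
    return kb.make_genome(4, 1.0, 50, (0.1, 0.9), seed=11)


@pytest.fixture(scope="session")
def small_founders(small_genome):
    return kb.simulate_founders(small_genome, 120, seed=12)


@pytest.fixture(scope="session")
def small_traits(small_genome, small_founders):
    t1 = kb.assign_trait(small_genome, 20, small_founders, seed=13, trait_id="trait1")
    t2 = kb.assign_trait(
        small_genome, 40, small_founders,
        exclude_indices=t1.qtl_indices, seed=14, trait_id="trait2",
    )
    return [t1, t2]


@pytest.fixture(scope="session")
def tiny_config():
    """A desk-scale breeding configuration for fast end-to-end runs."""
    return kb.BreedingConfig(
        n_chromosomes=4,
        markers_per_chromosome=50,
        qtl_count_1=20,
        qtl_count_2=40,
        historical_generations=3,
        negative_control_loci=60,
        bayesb_iterations=150,
        bayesb_burn_in=50,
        master_seed=21,
    )


@pytest.fixture
def rng():
    return np.random.default_rng(0)
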