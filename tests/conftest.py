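import numpy as np
import pytest

from tdaracne.simulate import SimulationParams, generate_random_network, simulate_expression


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_matrix():
    """A 5-gene, 30-point synthetic matrix with its generating structure."""
    params = SimulationParams(n_genes=5, n_timepoints=30, noise_variance=0.02, seed=7)
    gen = np.random.default_rng(7)
    structure = generate_random_network(params, rng=gen)
    matrix = simulate_expression(structure, params, rng=gen)
    return matrix, structure


#: Reduced bootstrap settings for unit tests that exercise the full
#: pipeline; acceptance tests use the defaults.
FAST_FIT = dict(n_boot=60, max_pairs_per_replicate=15)
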