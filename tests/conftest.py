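import numpy as np
import pytest

from netdrift import InteractionNetwork, SimulationConfig, initialize_population


@pytest.fixture
def single_node_net():
    """A lone subpopulation (no neighbors): pure within-group drift."""
    return InteractionNetwork(n_nodes=1, edges=frozenset())


@pytest.fixture
def two_node_net():
    return InteractionNetwork(n_nodes=2, edges=frozenset({(0, 1)}))


def random_population(rng: np.random.Generator, max_s: int = 6, max_size: int = 8):
    """A random small TraitPopulation for brute-force statistic checks."""
    S = int(rng.integers(1, max_s + 1))
    sizes = rng.integers(1, max_size + 1, size=S)
    N = int(sizes.sum())
    cfg = SimulationConfig(N=N, S=S, T=1, A0=1, R=1)
    pop = initialize_population(cfg)
    # overwrite with arbitrary sizes/traits (keeps the grouped layout)
    starts = np.concatenate([[0], np.cumsum(sizes)[:-1]]).astype(np.int64)
    pop.subpop_sizes = sizes.astype(np.int64)
    pop.subpop_start = starts
    pop.subpop_of = np.repeat(np.arange(S, dtype=np.int64), sizes)
    pop.traits = rng.integers(0, max(2, N // 2), size=N).astype(np.int64)
    pop.next_label = int(pop.traits.max()) + 1
    return pop
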