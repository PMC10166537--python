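import numpy as np
import pytest

from hyperphylo.simulate import SimulationConfig, random_tree, simulate_alignment


@pytest.fixture
def quartet_tree():
    """The quartet ((A:1,B:2):1,(C:3,D:4)) as a distance matrix + labels."""
    D = np.array(
        [
            [0, 3, 5, 6],
            [3, 0, 6, 7],
            [5, 6, 0, 7],
            [6, 7, 7, 0],
        ],
        dtype=float,
    )
    return D, list("ABCD")


@pytest.fixture
def small_tree():
    T = random_tree(SimulationConfig(n_taxa=5, seed=7))
    return T


@pytest.fixture
def small_alignment(small_tree):
    return simulate_alignment(small_tree, 10, seed=2)


def well_separated_tree(n_taxa, seed, min_edge=0.05):
    """Random tree with every edge at least min_edge long."""
    T = random_tree(SimulationConfig(n_taxa=n_taxa, seed=seed))
    T.lengths = T.lengths + min_edge
    return T
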