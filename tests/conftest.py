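import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from phyloconv import Phylogeny, SimulationConfig, SubstitutionModel, simulate_dataset


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def balanced4():
    """((A,B),(C,D)) with unit branch lengths."""
    return Phylogeny.from_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def binary_model():
    return SubstitutionModel.binary(0.3, 0.3)


@pytest.fixture(scope="session")
def small_dataset():
    """50-tip, 200-site neutral dataset reused across read-only tests."""
    return simulate_dataset(
        SimulationConfig(n_tips=50, n_sites=200, gain_rate=0.15, loss_rate=0.15, seed=11)
    )


def random_small_tree(rng, n_tips=5):
    """Random topology/branch-length tree for enumeration oracles."""
    from phyloconv import simulate_tree

    t = simulate_tree(int(n_tips), rng=rng)
    t.blen[:-1] = rng.uniform(0.05, 2.0, size=t.n_nodes - 1)
    return t


def random_reversible_model(rng, k=4):
    """Random small-alphabet reversible model for oracle tests."""
    alphabet = "ABCD"[:k]
    s = rng.uniform(0.2, 2.0, size=(k, k))
    s = (s + s.T) / 2
    np.fill_diagonal(s, 0.0)
    pi = rng.dirichlet(np.full(k, 2.0))
    return SubstitutionModel(alphabet, s, pi)
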