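import dendropy
import numpy as np
import pytest

from exomertrace.io import AMINO_ACIDS, SequenceRecord, read_newick
from exomertrace.simulate import (
    DEFAULT_NEO_CLADE,
    SimulationConfig,
    default_species_tree,
    simulate_family,
)


@pytest.fixture
def rng():
    return np.random.default_rng(42)


@pytest.fixture
def four_tip_tree():
    return read_newick("((A:1,B:2):1,(C:3,D:4):1);")


@pytest.fixture
def species_tree():
    return default_species_tree()


@pytest.fixture
def zero_divergence_family():
    """12-taxon family with negligible divergence: branch lengths ~0."""
    tree = default_species_tree(0.001)
    cfg = SimulationConfig(
        species_tree=tree, dup_rate=0.0, loss_rate=0.0, root_length=120,
        n_decoys=10, seed=11,
    )
    return simulate_family(cfg), cfg


def random_protein(rng, n):
    return "".join(rng.choice(list(AMINO_ACIDS), size=n))


def random_record(rng, i, n=None):
    n = n or int(rng.integers(20, 60))
    return SequenceRecord(id=f"s{i}", residues=random_protein(rng, n))


def random_tree(rng, n_tips):
    """Random binary tree with exponential branch lengths (dendropy)."""
    taxa = dendropy.TaxonNamespace([f"t{i}" for i in range(n_tips)])
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0, death_rate=0.0, num_extant_tips=n_tips,
        taxon_namespace=taxa, rng=_PyRandom(rng),
    )
    for edge in tree.preorder_edge_iter():
        if edge.length is None or edge.length <= 0:
            edge.length = float(rng.uniform(0.05, 0.5))
    tree.is_rooted = True
    return tree


class _PyRandom:
    """Adapter exposing the stdlib-random surface dendropy expects."""

    def __init__(self, rng):
        self._rng = rng

    def uniform(self, a, b):
        return float(self._rng.uniform(a, b))

    def random(self):
        return float(self._rng.random())

    def expovariate(self, lam):
        return float(self._rng.exponential(1.0 / lam))

    def sample(self, population, k):
        idx = self._rng.choice(len(population), size=k, replace=False)
        return [population[i] for i in idx]

    def choice(self, seq):
        return seq[int(self._rng.integers(len(seq)))]

    def shuffle(self, x):
        self._rng.shuffle(x)

    def randint(self, a, b):
        return int(self._rng.integers(a, b + 1))

    def gauss(self, mu, sigma):
        return float(self._rng.normal(mu, sigma))
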