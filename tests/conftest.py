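import numpy as np
import pytest

from mscbench import species_sim
from mscbench.treeio import SpeciesTree


@pytest.fixture
def rng():
    return np.random.default_rng(20231115)


def random_species_tree(n, rng, ne=1.0):
    """A random Yule species tree with constant Ne, for fixture use."""
    tree = species_sim.simulate_yule(n, 1.0, rng)
    species_sim.assign_population_sizes(
        tree, species_sim.PopulationModel(kind="constant", value=ne), rng
    )
    return tree


@pytest.fixture
def three_species_tree():
    """Asymmetric ((A,B),C) species tree with unit Ne everywhere."""
    from mscbench.treeio import Node

    a, b, c = Node("A", 0.0), Node("B", 0.0), Node("C", 0.0)
    ab = Node(None, 1.0)
    ab.add_child(a)
    ab.add_child(b)
    root = Node(None, 2.0)
    root.add_child(ab)
    root.add_child(c)
    tree = SpeciesTree(root)
    tree.pop_sizes = {node: 1.0 for node in tree.nodes()}
    return tree
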