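"""Shared fixtures: a small named taxonomy tree and default config."""

from __future__ import annotations

import numpy as np
import pytest

from lineagescan import RunConfig, SpeciesTree
from lineagescan.trees import GeneTree, Node


@pytest.fixture
def config() -> RunConfig:
    return RunConfig()


@pytest.fixture
def cetacean_tree() -> SpeciesTree:
    """Ultrametric taxonomy path Cetacea > Odontoceti > Delphinidae >
    Orcinus > Orcinus orca, padded with sister leaves to keep nodes binary.
    """
    newick = (
        "((((('Orcinus orca':5,Tursiops:5)Orcinus:5,Phocoena:10)"
        "Delphinidae:5,Physeter:15)Odontoceti:5,Mysticeti:20)Cetacea:5,"
        "Hippopotamus:25)Artiodactyla;"
    )
    return SpeciesTree.from_newick(newick)


def random_species_tree(rng: np.random.Generator, max_leaves: int = 6) -> SpeciesTree:
    from lineagescan import simulate_species_tree

    n = int(rng.integers(2, max_leaves + 1))
    return simulate_species_tree(n, 100.0, rng)


def random_gene_tree(
    rng: np.random.Generator, species: list[str], max_leaves: int = 8
) -> GeneTree:
    """Random binary gene tree whose leaves sample species with repeats."""
    n = int(rng.integers(2, max_leaves + 1))
    leaves = [
        Node(label=f"{species[int(rng.integers(len(species)))]}|g{i}",
             length=float(rng.uniform(0.01, 1.0)))
        for i in range(n)
    ]
    counter = 0
    nodes = leaves[:]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False).tolist())
        right = nodes.pop(j)
        left = nodes.pop(i)
        counter += 1
        parent = Node(label=f"i{counter}", length=float(rng.uniform(0.01, 1.0)))
        for child in (left, right):
            child.parent = parent
            parent.children.append(child)
        nodes.append(parent)
    nodes[0].length = 0.0
    return GeneTree(nodes[0])
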