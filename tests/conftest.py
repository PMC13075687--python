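"""Shared fixtures: small hand-built trees and randomized tree generators."""

import dendropy
import numpy as np
import pytest

from divscape import Phylogeny, read_newick


@pytest.fixture
def cherry():
    return read_newick("(A:1,B:1);")


@pytest.fixture
def three_tip():
    return read_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def balanced_four():
    return read_newick("((A:1,B:1):1,(C:1,D:1):1);")


def random_ultrametric(n_tips: int, seed: int, birth_rate: float = 1.0) -> Phylogeny:
    """A Yule tree with ``n_tips`` extant tips (branch lengths in Ma)."""
    import random as pyrandom
    pr = pyrandom.Random(seed)
    t = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=birth_rate, death_rate=0.0, num_extant_tips=n_tips,
        rng=pr)
    # the simulation stops at a speciation event, leaving zero pendant
    # edges; extend every leaf by the same waiting time to keep the tree
    # ultrametric with strictly positive branch lengths
    extra = pr.expovariate(n_tips * birth_rate)
    for leaf in t.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    t.purge_taxon_namespace()
    for i, leaf in enumerate(t.leaf_node_iter()):
        leaf.taxon.label = f"t{i}"
    return read_newick(t.as_string(schema="newick").strip())


def random_tree(n_tips: int, seed: int) -> Phylogeny:
    """A random non-ultrametric binary tree with exponential branch lengths."""
    rng = np.random.default_rng(seed)
    parent = [-1]
    length = [np.nan]
    labels = [None]
    tips = [0]
    while len(tips) < n_tips:
        v = tips.pop(rng.integers(len(tips)))
        for _ in range(2):
            parent.append(v)
            length.append(float(rng.exponential(1.0) + 1e-3))
            labels.append(None)
            tips.append(len(parent) - 1)
    for i, v in enumerate(tips):
        labels[v] = f"t{i}"
    return Phylogeny(parent, length, labels)
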