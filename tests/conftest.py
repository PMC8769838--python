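"""Shared fixtures and independent oracles.

The oracles here deliberately avoid the code paths they check: patristic
distances are recomputed by walking parent pointers to the LCA, and
MPD/MNTD by naive double loops over the oracle distances.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
import pytest

from ethnophylo import (
    CommunitySample,
    EfficacyMatrix,
    Phylogeny,
    default_categories,
    parse_newick,
    simulate_yule_tree,
)

BALANCED4 = "((a:1,b:1):1,(c:1,d:1):1);"
CHERRY = "((a:1,b:1):0);"
CATERPILLAR5 = "((((a:1,b:1):1,c:2):1,d:3):1,e:4);"


@pytest.fixture
def balanced4() -> Phylogeny:
    return parse_newick(BALANCED4)


@pytest.fixture
def caterpillar5() -> Phylogeny:
    return parse_newick(CATERPILLAR5)


# ---------------------------------------------------------------------------
# oracles


def oracle_pairwise_distance(tree: Phylogeny, a: str, b: str) -> float:
    """Patristic distance by explicit parent-walks to the LCA."""
    nodes = {
        leaf.taxon.label: leaf for leaf in tree.dendropy_tree.leaf_node_iter()
    }
    up_a = {}
    node, acc = nodes[a], 0.0
    while node.parent_node is not None:
        acc += node.edge.length
        node = node.parent_node
        up_a[id(node)] = acc
    node, acc = nodes[b], 0.0
    while node.parent_node is not None:
        acc += node.edge.length
        node = node.parent_node
        if id(node) in up_a:
            return acc + up_a[id(node)]
    raise AssertionError("no common ancestor found")


def oracle_distance_matrix(tree: Phylogeny) -> dict[tuple[str, str], float]:
    out = {}
    for a, b in itertools.combinations(tree.tip_labels, 2):
        d = oracle_pairwise_distance(tree, a, b)
        out[(a, b)] = d
        out[(b, a)] = d
    for a in tree.tip_labels:
        out[(a, a)] = 0.0
    return out


def oracle_mpd(tree: Phylogeny, members) -> float:
    pairs = list(itertools.combinations(members, 2))
    return sum(oracle_pairwise_distance(tree, a, b) for a, b in pairs) / len(pairs)


def oracle_mntd(tree: Phylogeny, members) -> float:
    total = 0.0
    for a in members:
        total += min(
            oracle_pairwise_distance(tree, a, b) for b in members if b != a
        )
    return total / len(members)


# ---------------------------------------------------------------------------
# generators


def random_tree_and_subset(seed: int, n_min=4, n_max=12):
    """One random Yule tree and a random tip subset of size >= 2."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(n_min, n_max + 1))
    tree = simulate_yule_tree(n, seed=int(rng.integers(2**31)))
    k = int(rng.integers(2, n + 1))
    members = tuple(
        tree.tip_labels[i] for i in rng.choice(n, size=k, replace=False)
    )
    return tree, members


def community_on(tree: Phylogeny, members) -> CommunitySample:
    return CommunitySample(tuple(members), tree.distance_matrix())


@pytest.fixture
def toy_matrix() -> EfficacyMatrix:
    """Five species x 15 categories with hand-set patterns."""
    cats = default_categories()
    rng = np.random.default_rng(42)
    values = pd.DataFrame(
        rng.integers(0, 2, size=(5, 15)),
        index=[f"Genus_sp{i}" for i in range(5)],
        columns=list(cats),
    )
    values.iloc[0] = 1  # one species treats everything
    values.iloc[1, 0] = 1  # ensure no all-zero row
    fams = pd.Series(
        ["FamA", "FamA", "FamB", "FamB", "FamB"], index=values.index
    )
    return EfficacyMatrix(values, fams, cats)
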