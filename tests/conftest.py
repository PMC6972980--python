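"""Shared fixtures and independent oracles.

The oracles here are deliberately naive re-derivations (double loops, path
sums through the MRCA) so that the vectorized implementations are checked
against something that cannot share their bugs.
"""

from __future__ import annotations

import numpy as np
import pytest

import phylossd as ps


# --- independent oracles ----------------------------------------------------

def morans_i_bruteforce(y, w) -> float:
    """Double-loop evaluation of the autocorrelation index definition."""
    y = np.asarray(y, dtype=float)
    n = y.size
    ybar = y.mean()
    s0 = 0.0
    num = 0.0
    for i in range(n):
        for j in range(n):
            s0 += w[i, j]
            num += w[i, j] * (y[i] - ybar) * (y[j] - ybar)
    den = sum((y[i] - ybar) ** 2 for i in range(n))
    return n / s0 * num / den


def cophenetic_bruteforce(tree: ps.PhyloTree) -> np.ndarray:
    """Patristic distances via d(i,j) = depth(i) + depth(j) - 2 depth(MRCA)."""
    t = tree.tree
    depth = {id(t.seed_node): 0.0}
    for node in t.preorder_node_iter():
        if node is not t.seed_node:
            depth[id(node)] = depth[id(node.parent_node)] + (node.edge.length or 0.0)
    chains = {}
    for leaf in t.leaf_node_iter():
        chain = []
        node = leaf
        while node is not None:
            chain.append(node)
            node = node.parent_node
        chains[leaf.taxon.label] = chain
    labels = tree.tips
    n = len(labels)
    d = np.zeros((n, n))
    for i in range(n):
        ids_i = [id(x) for x in chains[labels[i]]]
        for j in range(i + 1, n):
            mrca = next(x for x in chains[labels[j]] if id(x) in ids_i)
            dij = (
                depth[id(chains[labels[i]][0])]
                + depth[id(chains[labels[j]][0])]
                - 2 * depth[id(mrca)]
            )
            d[i, j] = d[j, i] = dij
    return d


# --- shared data ------------------------------------------------------------

# 8-tip tree and trait vector used for the frozen cross-implementation checks
ORACLE_NEWICK = "(((A:1,B:1):2,(C:1.5,D:1.5):1.5):1,((E:0.8,F:0.8):2.2,(G:2,H:2):1):1);"
ORACLE_TRAITS = {"A": 2.3, "B": 1.9, "C": 0.4, "D": 0.8,
                 "E": -1.2, "F": -0.7, "G": 3.1, "H": 2.6}


@pytest.fixture(scope="session")
def oracle_tree() -> ps.PhyloTree:
    return ps.parse_newick(ORACLE_NEWICK)


@pytest.fixture(scope="session")
def oracle_traits(oracle_tree) -> np.ndarray:
    return np.array([ORACLE_TRAITS[t] for t in oracle_tree.tips])


@pytest.fixture(scope="session")
def hypothetical_1():
    return ps.make_fixture("hypothetical_1")


@pytest.fixture(scope="session")
def hypothetical_2():
    return ps.make_fixture("hypothetical_2")


def random_trees(n_trees: int, max_tips: int = 30, seed: int = 0):
    """Seeded stream of random trees across models and sizes."""
    rng = np.random.default_rng(seed)
    for _ in range(n_trees):
        n = int(rng.integers(3, max_tips + 1))
        model = rng.choice(["yule", "coalescent", "balanced"])
        yield ps.random_tree(
            ps.SimulationConfig(n_tips=n, tree_model=str(model),
                                seed=int(rng.integers(2**31 - 1)))
        )
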