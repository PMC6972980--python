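"""Synthetic trees and endpoint datasets with controlled phylogenetic signal.

Provides seeded random trees, multivariate-normal log-endpoint simulation
with a Brownian-motion tree covariance whose off-diagonals are scaled by a
signal parameter lambda (lambda = 0: iid null; lambda = 1: pure BM), and the
two small hypothetical chlorpyrifos datasets shipped as fixtures.

The generator emulates what the SSD analysis assumes: natural-log endpoints
that are jointly normal across species, with dependence induced only through
shared ancestry. It does not emulate endpoint measurement error, censoring,
or between-study heterogeneity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import dendropy
import numpy as np
import pandas as pd

from .data_io import PhyloTree, ToxicityTable, ValidationError, parse_newick
from .signal import bm_covariance

__all__ = [
    "SimulationConfig",
    "random_tree",
    "simulate_traits",
    "simulate_dataset",
    "make_fixture",
]


@dataclass
class SimulationConfig:
    """Parameters of one simulated dataset.

    Defaults mirror the scale of the case-study data: a few dozen species
    (the real datasets span 9-73), unit BM rate on the log-concentration
    scale, and a log mean of 2 (an HC50 near e^2 ~ 7.4 in concentration
    units, comparable to the chlorpyrifos all-aquatic HC50 of ~8 ug/L).
    """

    n_tips: int = 30
    tree_model: Literal["yule", "coalescent", "balanced", "star"] = "yule"
    trait_model: Literal["bm", "bm_lambda", "iid"] = "bm"
    sigma2: float = 1.0
    lam: float = 1.0
    mean_log: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_tips < 3:
            raise ValidationError("need at least 3 tips")
        if self.sigma2 <= 0:
            raise ValidationError("sigma2 must be positive")
        if not 0.0 <= self.lam <= 1.0:
            raise ValidationError("lambda must be in [0, 1]")


def _star_newick(n: int) -> str:
    return "(" + ",".join(f"t{i+1}:1" for i in range(n)) + ");"


def _balanced_newick(n: int) -> str:
    labels = iter(f"t{i+1}" for i in range(n))

    def build(k: int) -> str:
        if k == 1:
            return f"{next(labels)}:1"
        left = k // 2
        return f"({build(left)},{build(k - left)}):1"

    return build(n) + ";"


def random_tree(config: SimulationConfig) -> PhyloTree:
    """Seeded random tree with positive branch lengths."""
    n = config.n_tips
    if config.tree_model == "star":
        return parse_newick(_star_newick(n))
    if config.tree_model == "balanced":
        return parse_newick(_balanced_newick(n))
    rng = np.random.default_rng(config.seed)
    if config.tree_model == "yule":
        # pure-birth: start with 2 lineages, split a uniformly chosen lineage
        # at exponential waiting times until n tips
        tree = dendropy.Tree()
        tree.seed_node.new_child(edge_length=0.0)
        tree.seed_node.new_child(edge_length=0.0)
        active = list(tree.seed_node.child_nodes())
        while len(active) < n:
            dt = rng.exponential(1.0 / len(active))
            for node in active:
                node.edge.length += dt
            k = rng.integers(len(active))
            parent = active.pop(k)
            c1 = parent.new_child(edge_length=0.0)
            c2 = parent.new_child(edge_length=0.0)
            active.extend([c1, c2])
        dt = rng.exponential(1.0 / len(active))
        for node in active:
            node.edge.length += dt
        ns = tree.taxon_namespace
        for i, leaf in enumerate(tree.leaf_node_iter()):
            leaf.taxon = ns.new_taxon(label=f"t{i+1}")
        return PhyloTree(tree)
    if config.tree_model == "coalescent":
        # Kingman-style: merge random lineage pairs at exponential times
        tree = dendropy.Tree()
        lineages = []
        for i in range(n):
            node = dendropy.Node(edge_length=0.0)
            lineages.append(node)
        while len(lineages) > 1:
            k = len(lineages)
            dt = rng.exponential(2.0 / (k * (k - 1)))
            for node in lineages:
                node.edge.length += dt
            i, j = rng.choice(k, size=2, replace=False)
            a, b = lineages[i], lineages[j]
            merged = dendropy.Node(edge_length=0.0)
            merged.add_child(a)
            merged.add_child(b)
            lineages = [x for idx, x in enumerate(lineages) if idx not in (i, j)]
            lineages.append(merged)
        root = lineages[0]
        tree.seed_node.add_child(root)
        root.edge.length = 0.0
        ns = tree.taxon_namespace
        for i, leaf in enumerate(tree.leaf_node_iter()):
            leaf.taxon = ns.new_taxon(label=f"t{i+1}")
        return PhyloTree(tree)
    raise ValidationError(f"unknown tree model {config.tree_model!r}")


def simulate_traits(tree: PhyloTree, config: SimulationConfig) -> np.ndarray:
    """Draw log endpoints: multivariate normal with covariance sigma2 * C_lambda.

    C is the BM covariance of the tree (shared root-path lengths); its
    off-diagonals are multiplied by lambda. ``trait_model='iid'`` forces
    lambda = 0; ``'bm'`` forces lambda = 1. The return is aligned to
    ``tree.tips``; exponentiate to obtain concentration-scale endpoints.
    """
    lam = {"bm": 1.0, "iid": 0.0}.get(config.trait_model, config.lam)
    C = bm_covariance(tree)
    Cl = lam * C
    np.fill_diagonal(Cl, np.diag(C))
    cov = config.sigma2 * Cl
    try:
        L = np.linalg.cholesky(cov + 1e-12 * np.eye(cov.shape[0]))
    except np.linalg.LinAlgError as exc:
        raise ValidationError("trait covariance not positive-definite") from exc
    rng = np.random.default_rng(config.seed)
    return config.mean_log + L @ rng.standard_normal(cov.shape[0])


def simulate_dataset(config: SimulationConfig) -> tuple[PhyloTree, ToxicityTable]:
    """Tree plus endpoint table drawn under the config (one seeded draw)."""
    tree = random_tree(config)
    logs = simulate_traits(tree, config)
    df = pd.DataFrame({"species": tree.tips, "endpoint": np.exp(logs)})
    return tree, ToxicityTable(df, units="sim")


# --- Printed hypothetical chlorpyrifos datasets -----------------------------

# (taxon group, species, geometric-mean effect concentration in ug/L)
_HYPOTHETICAL_1 = [
    ("Alga", "Skeletonema costatum", 298.0),
    ("Alga", "Thalassiosira pseudonana", 148.0),
    ("Amphibian", "Rana clamitans", 236.0),
    ("Amphibian", "Rana dalmatina", 5174.0),
    ("Crustacean", "Daphnia longispina", 0.3),
    ("Crustacean", "Macrobrachium rosenbergii", 0.3),
    ("Fish", "Lepomis macrochirus", 10.0),
    ("Fish", "Leuciscus idus", 10.0),
    ("Insect", "Corixa punctata", 2.0),
    ("Insect", "Sigara arguta", 2.16),
    ("Mollusk", "Lampsilis siliquoidea", 250.0),
    ("Mollusk", "Mytilus galloprovincialis", 154.0),
    ("Rotifer", "Brachionus calyciflorus", 12000.0),
]

_HYPOTHETICAL_2 = [
    ("Crustacean", "Ceriodaphnia dubia", 0.054),
    ("Crustacean", "Daphnia carinata", 0.19),
    ("Crustacean", "Daphnia longispina", 0.3),
    ("Insect", "Corixa punctata", 2.0),
    ("Insect", "Sigara arguta", 2.16),
    ("Insect", "Notonecta maculata", 7.97),
    ("Fish", "Lepomis macrochirus", 10.0),
    ("Fish", "Sander vitreus", 18.0),
    ("Fish", "Melanotaenia fluviatilis", 122.0),
    ("Alga", "Thalassiosira pseudonana", 148.0),
    ("Alga", "Skeletonema costatum", 298.0),
    ("Alga", "Dunaliella tertiolecta", 769.0),
]

_FIXTURES = {"hypothetical_1": _HYPOTHETICAL_1, "hypothetical_2": _HYPOTHETICAL_2}


def _taxonomy_tree(records: list[tuple[str, str, float]]) -> PhyloTree:
    groups: dict[str, list[str]] = {}
    for group, species, _ in records:
        groups.setdefault(group, []).append(species)
    parts = []
    for group, members in groups.items():
        tips = ",".join(f"'{s}':1" for s in members)
        parts.append(f"({tips}):1" if len(members) > 1 else f"{tips}")
    return parse_newick("(" + ",".join(parts) + ");")


def make_fixture(name: str) -> tuple[PhyloTree, ToxicityTable]:
    """Return one of the two hypothetical chlorpyrifos datasets.

    Endpoint tables carry the published geometric-mean effect concentrations
    verbatim. The accompanying trees are SYNTHETIC taxonomy-shaped
    stand-ins (taxon-group -> species hierarchy with unit branch lengths),
    not the original taxonomy-derived trees, which were never published in
    machine-readable form; analyses depending on exact tree shape should
    treat their signal values as illustrative.
    """
    if name not in _FIXTURES:
        raise ValidationError(
            f"unknown fixture {name!r}; available: {sorted(_FIXTURES)}"
        )
    records = _FIXTURES[name]
    df = pd.DataFrame(
        {
            "species": [s for _, s, _ in records],
            "endpoint": [v for _, _, v in records],
            "group": [g for g, _, _ in records],
        }
    )
    return _taxonomy_tree(records), ToxicityTable(df, units="ug/L")
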