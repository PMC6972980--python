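"""Tree and toxicity-table input/output.

Reads rooted Newick trees (e.g. phyloT taxonomy exports), computes patristic
(cophenetic) distance matrices, reads delimited toxicity-endpoint tables with
geometric-mean aggregation of replicate records, and aligns the two by species
label so downstream signal statistics see one endpoint per tip, in tip order.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger("phylossd")

__all__ = [
    "PhyloTree",
    "DistanceMatrix",
    "ToxicityTable",
    "JoinReport",
    "ValidationError",
    "normalize_label",
    "parse_newick",
    "read_newick",
    "write_newick",
    "cophenetic_matrix",
    "read_toxicity_table",
    "join_tree_and_table",
]


class ValidationError(ValueError):
    """Input fails a domain precondition (as opposed to a parse failure)."""


def normalize_label(label: str) -> str:
    """Normalize a species label for tree/table matching.

    Strips surrounding quotes and whitespace, maps underscores to spaces and
    collapses internal whitespace runs. Matching stays case-sensitive:
    taxonomy names are consistently capitalized, and case-folding could merge
    genuinely distinct labels.
    """
    label = label.strip().strip("'\"").replace("_", " ")
    return re.sub(r"\s+", " ", label).strip()


@dataclass
class PhyloTree:
    """A rooted tree with named tips and nonnegative branch lengths.

    Thin wrapper around a :class:`dendropy.Tree`; tip labels are normalized
    once at construction. Multifurcations are accepted as-is (taxonomy-derived
    trees are typically multifurcating).
    """

    tree: dendropy.Tree

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for leaf in self.tree.leaf_node_iter():
            if leaf.taxon is None or not leaf.taxon.label:
                raise ValidationError("tree contains an unnamed tip")
            label = normalize_label(leaf.taxon.label)
            if not label:
                raise ValidationError("tree contains an empty tip label")
            if label in seen:
                raise ValidationError(f"duplicate tip label after normalization: {label!r}")
            seen.add(label)
            leaf.taxon.label = label
        for edge in self.tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise ValidationError(f"negative branch length {edge.length}")

    @property
    def tips(self) -> list[str]:
        return [leaf.taxon.label for leaf in self.tree.leaf_node_iter()]

    @property
    def n_tips(self) -> int:
        return sum(1 for _ in self.tree.leaf_node_iter())

    def prune_to(self, labels: Iterable[str]) -> "PhyloTree":
        """Return a copy pruned to the given tip labels."""
        keep = set(labels)
        clone = dendropy.Tree(self.tree)
        taxa = [t for t in clone.taxon_namespace if t.label in keep]
        clone.retain_taxa(taxa)
        return PhyloTree(clone)

    def copy(self) -> "PhyloTree":
        return PhyloTree(dendropy.Tree(self.tree))


def parse_newick(text: str, default_branch_length: float = 1.0) -> PhyloTree:
    """Parse a Newick string into a :class:`PhyloTree`.

    Edges without a stated length receive ``default_branch_length`` (phyloT
    taxonomy trees carry implicit unit lengths); the root edge gets 0.

    Raises
    ------
    ValueError
        Malformed Newick (dendropy's error names the offending position).
    ValidationError
        Duplicate or empty tip labels, or negative branch lengths.
    """
    try:
        tree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy raises several error types
        if isinstance(exc, ValidationError):
            raise
        if "Multiple occurrences of the same taxa" in str(exc):
            raise ValidationError(f"duplicate tip labels: {exc}") from exc
        raise ValueError(f"malformed Newick: {exc}") from exc
    for edge in tree.preorder_edge_iter():
        if edge.length is None:
            edge.length = 0.0 if edge.head_node is tree.seed_node else default_branch_length
    return PhyloTree(tree)


def read_newick(path, default_branch_length: float = 1.0) -> PhyloTree:
    """Read a Newick file from ``path``."""
    with open(path) as fh:
        text = fh.read()
    tree = parse_newick(text, default_branch_length=default_branch_length)
    logger.info("read tree with %d tips from %s", tree.n_tips, path)
    return tree


def write_newick(tree: PhyloTree, path=None) -> str:
    """Serialize to Newick; optionally also write to ``path``."""
    text = tree.tree.as_string(schema="newick", suppress_rooting=True).strip()
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text + "\n")
    return text


@dataclass
class DistanceMatrix:
    """Symmetric patristic distance matrix in a fixed tip order."""

    labels: list[str]
    d: np.ndarray

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        n = len(self.labels)
        if self.d.shape != (n, n):
            raise ValidationError("distance matrix shape does not match labels")
        if not np.allclose(self.d, self.d.T):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(self.d) != 0):
            raise ValidationError("distance matrix diagonal must be zero")

    @property
    def n(self) -> int:
        return len(self.labels)

    def off_diagonal(self) -> np.ndarray:
        mask = ~np.eye(self.n, dtype=bool)
        return self.d[mask]


def cophenetic_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Patristic distances between all tip pairs, in tip order.

    d(i, j) is the sum of branch lengths on the path between tips i and j.
    """
    labels = tree.tips
    n = len(labels)
    if n < 2:
        raise ValidationError("cophenetic matrix needs at least 2 tips")
    pdm = tree.tree.phylogenetic_distance_matrix()
    taxa = {leaf.taxon.label: leaf.taxon for leaf in tree.tree.leaf_node_iter()}
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[labels[i]], taxa[labels[j]])
    return DistanceMatrix(labels, d)


@dataclass
class ToxicityTable:
    """One positive endpoint per species, after geometric-mean aggregation.

    ``data`` has columns ``species`` (normalized label), ``endpoint``
    (concentration/dose, > 0) and optionally ``group`` (taxon tag).
    """

    data: pd.DataFrame
    units: str = ""

    def __post_init__(self) -> None:
        if "species" not in self.data.columns or "endpoint" not in self.data.columns:
            raise ValidationError("toxicity table needs 'species' and 'endpoint' columns")
        if len(self.data) == 0:
            raise ValidationError("toxicity table is empty")
        bad = self.data[~(self.data["endpoint"] > 0)]
        if len(bad):
            raise ValidationError(
                f"nonpositive endpoints for species: {sorted(bad['species'])}"
            )
        if self.data["species"].duplicated().any():
            dups = sorted(self.data.loc[self.data["species"].duplicated(), "species"])
            raise ValidationError(f"duplicate species after aggregation: {dups}")
        self.data = self.data.reset_index(drop=True)

    @property
    def species(self) -> list[str]:
        return list(self.data["species"])

    @property
    def endpoints(self) -> np.ndarray:
        return self.data["endpoint"].to_numpy(dtype=float)

    @property
    def log_endpoints(self) -> np.ndarray:
        """Natural-log endpoints — the SSD sample."""
        return np.log(self.endpoints)

    @property
    def n(self) -> int:
        return len(self.data)

    def reorder(self, labels: Sequence[str]) -> "ToxicityTable":
        missing = set(labels) - set(self.species)
        if missing:
            raise ValidationError(f"species not in table: {sorted(missing)}")
        df = self.data.set_index("species").loc[list(labels)].reset_index()
        return ToxicityTable(df, units=self.units)


def aggregate_geometric_mean(df: pd.DataFrame) -> pd.DataFrame:
    """Collapse replicate records per species to the geometric mean."""
    out = (
        df.groupby("species", sort=False)
        .agg(
            endpoint=("endpoint", lambda v: float(np.exp(np.mean(np.log(v))))),
            **({"group": ("group", "first")} if "group" in df.columns else {}),
        )
        .reset_index()
    )
    return out


def read_toxicity_table(path_or_buffer, units: str = "", species_col: str = "species",
                        endpoint_col: str = "endpoint", group_col: str = "group",
                        sep: str | None = None) -> ToxicityTable:
    """Read a CSV/TSV endpoint table and aggregate replicates.

    The file needs a header with a species column and a positive numeric
    endpoint column; an optional group column carries taxon tags. Replicate
    records for a species are collapsed to their geometric mean. The
    delimiter is sniffed when ``sep`` is None.
    """
    df = pd.read_csv(path_or_buffer, sep=sep, engine="python")
    if species_col not in df.columns or endpoint_col not in df.columns:
        raise ValidationError(
            f"expected columns {species_col!r} and {endpoint_col!r}, got {list(df.columns)}"
        )
    rename = {species_col: "species", endpoint_col: "endpoint"}
    if group_col in df.columns:
        rename[group_col] = "group"
    df = df.rename(columns=rename)[list(rename.values())]
    if len(df) == 0:
        raise ValidationError("toxicity table is empty")
    df["species"] = df["species"].astype(str).map(normalize_label)
    df["endpoint"] = pd.to_numeric(df["endpoint"], errors="raise")
    bad = df.index[~(df["endpoint"] > 0)].tolist()
    if bad:
        raise ValidationError(f"nonpositive endpoint values at rows {bad}")
    n_raw = len(df)
    df = aggregate_geometric_mean(df)
    logger.info("read %d endpoint records -> %d species", n_raw, len(df))
    return ToxicityTable(df, units=units)


@dataclass
class JoinReport:
    """Names dropped on either side when aligning a tree and a table."""

    dropped_tips: list[str] = field(default_factory=list)
    dropped_species: list[str] = field(default_factory=list)


def join_tree_and_table(
    tree: PhyloTree, table: ToxicityTable, min_overlap: int = 3
) -> tuple[PhyloTree, ToxicityTable, JoinReport]:
    """Align a tree and an endpoint table on shared species labels.

    Prunes the tree to the intersection, restricts and reorders the table to
    tip order, and reports names dropped on both sides. With fewer than
    ``min_overlap`` shared species a signal test is meaningless, so that is
    an error.
    """
    tips = set(tree.tips)
    species = set(table.species)
    shared = tips & species
    report = JoinReport(
        dropped_tips=sorted(tips - species),
        dropped_species=sorted(species - tips),
    )
    if len(shared) < min_overlap:
        raise ValidationError(
            f"only {len(shared)} species shared between tree and table "
            f"(need >= {min_overlap})"
        )
    pruned = tree.prune_to(shared) if report.dropped_tips else tree.copy()
    aligned = table.reorder(pruned.tips)
    for name in report.dropped_tips:
        logger.warning("tip dropped (no endpoint): %s", name)
    for name in report.dropped_species:
        logger.warning("species dropped (not in tree): %s", name)
    return pruned, aligned, report
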