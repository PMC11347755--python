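"""Species trees and the phylogenetic correlation matrix.

A Newick tree is made ultrametric with Grafen's method (node height =
((tips below - 1)/(S - 1))^rho, total depth 1) and converted to the
species-by-species correlation matrix whose (i, j) entry is the fraction
of root-to-tip path the two species share.
"""

from __future__ import annotations

import dataclasses

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PhyloParseError",
    "SpeciesTree",
    "PhyloCorrelation",
    "parse_newick",
    "read_newick",
    "grafen_branch_lengths",
    "correlation_matrix",
]

ULTRAMETRIC_TOL = 1e-9


class PhyloParseError(ValueError):
    """Raised for malformed Newick input."""


@dataclasses.dataclass
class SpeciesTree:
    """Thin wrapper around a rooted dendropy tree."""

    tree: dendropy.Tree

    @property
    def tip_labels(self) -> tuple[str, ...]:
        return tuple(leaf.taxon.label for leaf in self.tree.leaf_node_iter())

    @property
    def n_tips(self) -> int:
        return len(self.tree.leaf_nodes())

    def as_newick(self) -> str:
        return self.tree.as_string(schema="newick", suppress_rooting=True).strip()

    def tip_depths(self) -> dict[str, float]:
        depths = {}
        for node in self.tree.preorder_node_iter():
            parent_depth = getattr(node.parent_node, "_depth", 0.0) if node.parent_node else 0.0
            node._depth = parent_depth + (node.edge.length or 0.0)
            if node.is_leaf():
                depths[node.taxon.label] = node._depth
        return depths

    def is_ultrametric(self, tol: float = ULTRAMETRIC_TOL) -> bool:
        depths = list(self.tip_depths().values())
        return max(depths) - min(depths) <= tol


@dataclasses.dataclass(frozen=True)
class PhyloCorrelation:
    """Symmetric species correlation matrix with unit diagonal."""

    ids: tuple[str, ...]
    matrix: np.ndarray

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=list(self.ids), columns=list(self.ids))

    def reorder(self, ids) -> "PhyloCorrelation":
        idx = [self.ids.index(i) for i in ids]
        return PhyloCorrelation(
            ids=tuple(ids), matrix=self.matrix[np.ix_(idx, idx)]
        )


def parse_newick(text: str) -> SpeciesTree:
    """Parse a Newick string into a rooted :class:`SpeciesTree`."""
    try:
        tree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        raise PhyloParseError(f"malformed Newick: {exc}") from exc
    labels = [leaf.taxon.label if leaf.taxon else None for leaf in tree.leaf_node_iter()]
    if any(lbl is None for lbl in labels):
        raise PhyloParseError("tree contains unlabelled tips")
    if len(set(labels)) != len(labels):
        dupes = sorted({x for x in labels if labels.count(x) > 1})
        raise PhyloParseError(f"duplicate tip labels: {dupes}")
    tree.is_rooted = True
    return SpeciesTree(tree=tree)


def read_newick(path) -> SpeciesTree:
    with open(path, "r", encoding="utf-8") as fh:
        return parse_newick(fh.read())


def grafen_branch_lengths(t: SpeciesTree, rho: float = 1.0) -> SpeciesTree:
    """Assign Grafen branch lengths: node height = ((tips-1)/(S-1))^rho.

    Tips sit at height 0 and the root at height 1, so the tree becomes
    ultrametric with total depth 1.
    """
    tree = t.tree.clone(depth=1)
    s = len(tree.leaf_nodes())
    if s < 2:
        raise ValueError("Grafen branch lengths require at least 2 tips")
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._ntips = 1
            node._height = 0.0
        else:
            node._ntips = sum(ch._ntips for ch in node.child_nodes())
            node._height = ((node._ntips - 1) / (s - 1)) ** rho
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            node.edge.length = None
        else:
            node.edge.length = node.parent_node._height - node._height
    return SpeciesTree(tree=tree)


def correlation_matrix(t: SpeciesTree) -> PhyloCorrelation:
    """Shared-depth-fraction correlation matrix of an ultrametric tree.

    A_ij = (depth of the most recent common ancestor of i and j) / total
    depth; diagonal is exactly 1.
    """
    if not t.is_ultrametric():
        raise ValueError(
            "tree is not ultrametric; run grafen_branch_lengths first"
        )
    tree = t.tree
    # node depths from root
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        pdepth = parent._cm_depth if parent is not None else 0.0
        node._cm_depth = pdepth + (node.edge.length or 0.0)
    leaves = list(tree.leaf_node_iter())
    labels = [leaf.taxon.label for leaf in leaves]
    index = {id(leaf): i for i, leaf in enumerate(leaves)}
    s = len(leaves)
    total_depth = max(leaf._cm_depth for leaf in leaves)
    if total_depth <= 0:
        raise ValueError("tree has zero depth")
    a = np.zeros((s, s))
    # each internal node sets A for tip pairs whose MRCA it is:
    # pairs drawn from different child subtrees
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            node._cm_tips = [index[id(node)]]
            continue
        groups = [ch._cm_tips for ch in node.child_nodes()]
        frac = node._cm_depth / total_depth
        for gi in range(len(groups)):
            for gj in range(gi + 1, len(groups)):
                ii = np.asarray(groups[gi])
                jj = np.asarray(groups[gj])
                a[np.ix_(ii, jj)] = frac
                a[np.ix_(jj, ii)] = frac
        node._cm_tips = [i for g in groups for i in g]
    np.fill_diagonal(a, 1.0)
    return PhyloCorrelation(ids=tuple(labels), matrix=a)
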