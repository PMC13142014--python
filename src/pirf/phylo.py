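"""Phylogenetic trees and cophenetic (patristic) distances.

A phylogenetic tree relates microbial features (OTUs/ASVs) through shared
ancestry: leaves are features, internal nodes common ancestors, and branch
lengths measure evolutionary divergence. The cophenetic (patristic) distance
between two leaves is the total branch length along the unique path
connecting them through their most recent common ancestor; it is the metric
on which phylogenetic clusters are built.

Newick I/O is delegated to :mod:`dendropy`; validation and the distance
computation are done here so that the metric's preconditions (unique leaf
labels, every edge carrying a non-negative length) are enforced explicitly.
"""

from __future__ import annotations

import os
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import dendropy
import numpy as np

from .errors import DataError, ValidationError

__all__ = ["PhyloTree", "DistanceMatrix", "read_newick", "cophenetic_matrix",
           "align_to_table"]


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with ordered labels."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "labels", tuple(self.labels))
        p = len(self.labels)
        if v.shape != (p, p):
            raise ValidationError(
                f"distance matrix shape {v.shape} does not match {p} labels")
        if not np.allclose(v, v.T, atol=1e-9):
            raise ValidationError("distance matrix is not symmetric")
        if np.any(np.diag(v) != 0):
            raise ValidationError("distance matrix diagonal is not zero")
        if np.any(v < 0):
            raise ValidationError("distance matrix has negative entries")

    @property
    def n(self) -> int:
        return len(self.labels)

    def index_of(self, label: str) -> int:
        return self.labels.index(label)

    def subset(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Restrict to ``labels`` in the given order."""
        idx = [self.labels.index(l) for l in labels]
        return DistanceMatrix(tuple(labels), self.values[np.ix_(idx, idx)])


class PhyloTree:
    """A validated rooted (or basally multifurcating) tree with branch lengths.

    Thin wrapper around a :class:`dendropy.Tree` that enforces the invariants
    the distance computation relies on: unique, non-empty leaf labels
    (whitespace-trimmed) and a non-negative length on every edge except the
    root's. Polytomies are allowed; the path-sum distance handles them
    directly, and because the cophenetic distance is root-invariant no
    rerooting is ever performed.
    """

    def __init__(self, tree: dendropy.Tree):
        # path-based distances are root-invariant, so treating the seed node
        # as the root is harmless and keeps downstream MRCA queries quiet
        tree.is_rooted = True
        self._tree = tree
        self._validate()

    # -- validation ------------------------------------------------------

    def _validate(self) -> None:
        seen = set()
        for leaf in self._tree.leaf_node_iter():
            label = None if leaf.taxon is None else leaf.taxon.label
            if label is None or not str(label).strip():
                raise ValidationError("tree contains a leaf with an empty label")
            label = str(label).strip()
            leaf.taxon.label = label
            if label in seen:
                raise ValidationError(f"duplicate leaf label: {label!r}")
            seen.add(label)
        root = self._tree.seed_node
        for node in self._tree.preorder_node_iter():
            if node is root:
                continue
            length = node.edge.length
            if length is None:
                raise ValidationError(
                    "edge without a branch length (distances undefined); "
                    "offending child node leads to leaves "
                    f"{[l.taxon.label for l in node.leaf_iter()][:3]}")
            if length < 0:
                raise ValidationError(f"negative branch length {length}")

    # -- basic accessors -------------------------------------------------

    @property
    def leaf_labels(self) -> tuple:
        return tuple(l.taxon.label for l in self._tree.leaf_node_iter())

    @property
    def n_leaves(self) -> int:
        return sum(1 for _ in self._tree.leaf_node_iter())

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick",
                                    suppress_rooting=True).strip()

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")

    # -- operations ------------------------------------------------------

    def prune_to(self, labels: Iterable[str]) -> "PhyloTree":
        """Return a copy pruned to exactly ``labels`` (path lengths preserved)."""
        keep = set(labels)
        missing = keep - set(self.leaf_labels)
        if missing:
            raise ValidationError(
                f"labels not in tree: {sorted(missing)}")
        clone = self._tree.clone(depth=1)
        taxa = [t for t in clone.taxon_namespace if t.label in keep]
        clone.retain_taxa(taxa)
        # retain_taxa suppresses unifurcations, summing the merged edge
        # lengths, so leaf-to-leaf path lengths are unchanged.
        clone.purge_taxon_namespace()
        return PhyloTree(clone)


def read_newick(source) -> PhyloTree:
    """Parse a single Newick tree from a path, open stream, or raw string.

    Branch lengths are preserved exactly as written; standard Newick quoting
    applies and underscores in unquoted labels are kept verbatim.
    """
    if hasattr(source, "read"):
        data = source.read()
    else:
        text = str(source)
        if os.path.exists(text):
            with open(text) as fh:
                data = fh.read()
        else:
            data = text
    if ";" not in data:
        raise ValidationError("malformed Newick: no ';' terminator found")
    try:
        tree = dendropy.Tree.get(
            data=data, schema="newick", preserve_underscores=True,
            suppress_internal_node_taxa=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise ValidationError(f"malformed Newick: {exc}") from exc
    return PhyloTree(tree)


def cophenetic_matrix(tree: PhyloTree) -> DistanceMatrix:
    """Pairwise cophenetic (patristic) distances between all leaves.

    Entry (a, b) is the total branch length on the unique path from leaf a to
    leaf b, i.e. depth(a) + depth(b) - 2*depth(MRCA(a, b)) in root-distance
    terms. Computed in O(p^2) by a single post-order sweep: leaf pairs whose
    MRCA is node v are exactly the pairs drawn from two different child
    subtrees of v.
    """
    labels = tree.leaf_labels
    p = len(labels)
    if p < 2:
        raise DataError("cophenetic distances require at least 2 leaves")
    index = {lab: i for i, lab in enumerate(labels)}

    dtree = tree.dendropy_tree
    root = dtree.seed_node
    depth = {}
    for node in dtree.preorder_node_iter():
        if node is root:
            depth[node] = 0.0
        else:
            depth[node] = depth[node.parent_node] + node.edge.length

    leaf_depth = np.empty(p)
    D = np.zeros((p, p))
    below: dict = {}
    for node in dtree.postorder_node_iter():
        if node.is_leaf():
            i = index[node.taxon.label]
            leaf_depth[i] = depth[node]
            below[node] = [i]
            continue
        children = [below.pop(c) for c in node.child_nodes()]
        dv = depth[node]
        for a in range(len(children)):
            for b in range(a + 1, len(children)):
                ia = np.asarray(children[a])
                ib = np.asarray(children[b])
                block = (leaf_depth[ia][:, None] + leaf_depth[ib][None, :]
                         - 2.0 * dv)
                D[np.ix_(ia, ib)] = block
                D[np.ix_(ib, ia)] = block.T
        below[node] = [i for ch in children for i in ch]
    return DistanceMatrix(labels, D)


def align_to_table(tree: PhyloTree, features: Sequence[str],
                   missing: str = "error") -> PhyloTree:
    """Prune ``tree`` to the features of a table.

    Features absent from the tree are an error by default (``missing="error"``)
    or dropped with a warning (``missing="warn"``); callers must then subset
    the table to ``result.leaf_labels``. An empty intersection is always an
    error.
    """
    if missing not in ("error", "warn"):
        raise ValidationError(f"missing must be 'error' or 'warn', got {missing!r}")
    features = [str(f).strip() for f in features]
    leaves = set(tree.leaf_labels)
    absent = [f for f in features if f not in leaves]
    present = [f for f in features if f in leaves]
    if not present:
        raise ValidationError(
            "no overlap between table features and tree leaves")
    if absent:
        if missing == "error":
            raise ValidationError(
                f"{len(absent)} features absent from the tree: "
                f"{absent[:10]}{'...' if len(absent) > 10 else ''}")
        warnings.warn(f"dropping {len(absent)} features absent from the tree",
                      stacklevel=2)
    return tree.prune_to(present)
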