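"""Array-backed phylogenetic tree with Newick I/O and branch-length accounting.

The same structure stores both dated phylogenies (rooted, ultrametric on
simulated data) and trait dendrograms from neighbour joining (unrooted;
anchored at an arbitrary internal node purely for storage).  Every diversity
statistic in this package is a sum over edges, so the anchor choice of an
unrooted tree never matters.

Nodes are kept in preorder: node 0 is the root/anchor and every child has a
larger index than its parent.  That ordering makes subtree accumulation a
single reversed sweep and root-to-tip accumulation a single forward sweep.
"""

from __future__ import annotations

import logging
from functools import cached_property
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = ["PhyloTree", "NewickParseError", "TreeValidationError",
           "read_newick", "write_newick", "total_branch_length"]


class NewickParseError(ValueError):
    """Raised when a Newick string cannot be parsed."""


class TreeValidationError(ValueError):
    """Raised when a tree violates a structural invariant."""


class PhyloTree:
    """Rooted (or anchor-rooted unrooted) tree with non-negative edge lengths.

    Parameters
    ----------
    parent
        Integer array, one entry per node in preorder; ``parent[0] == -1``
        and ``parent[i] < i`` for every other node.
    length
        Edge length from each node to its parent.  The root entry is ignored
        and stored as 0.  Negative inputs (e.g. from neighbour joining) are
        clamped to 0 with a logged warning.
    labels
        One label per node; tips must carry unique non-empty labels, internal
        labels are optional.
    rooted
        False for trees whose root is only a storage anchor.
    """

    def __init__(self, parent: Sequence[int], length: Sequence[float],
                 labels: Sequence[str | None], rooted: bool = True):
        self.parent = np.asarray(parent, dtype=np.int64)
        self.length = np.asarray(length, dtype=np.float64).copy()
        self.labels = list(labels)
        self.rooted = bool(rooted)
        self._validate()

    # ------------------------------------------------------------------ setup
    def _validate(self) -> None:
        n = self.parent.size
        if not (self.length.size == n and len(self.labels) == n):
            raise TreeValidationError("parent/length/labels size mismatch")
        if n == 0 or self.parent[0] != -1:
            raise TreeValidationError("node 0 must be the root (parent -1)")
        if n > 1 and not ((self.parent[1:] >= 0) & (self.parent[1:] < np.arange(1, n))).all():
            raise TreeValidationError("nodes must be in preorder (parent index < child index)")
        if np.any(self.length < 0):
            logger.warning("clamping %d negative edge length(s) to 0",
                           int((self.length < 0).sum()))
            self.length = np.maximum(self.length, 0.0)
        self.length[0] = 0.0  # root edge excluded from all sums
        if not np.all(np.isfinite(self.length)):
            raise TreeValidationError("edge lengths must be finite")
        tips = self.tip_indices
        if tips.size < 2:
            raise TreeValidationError("a tree needs at least 2 tips")
        tip_labels = [self.labels[i] for i in tips]
        if any(lab is None or lab == "" for lab in tip_labels):
            raise TreeValidationError("every tip must carry a non-empty label")
        if len(set(tip_labels)) != len(tip_labels):
            dupes = sorted({x for x in tip_labels if tip_labels.count(x) > 1})
            raise TreeValidationError(f"duplicate tip labels: {dupes}")

    # ------------------------------------------------------------- properties
    @cached_property
    def n_nodes(self) -> int:
        return int(self.parent.size)

    @cached_property
    def is_tip(self) -> np.ndarray:
        mask = np.ones(self.n_nodes, dtype=bool)
        mask[self.parent[self.parent >= 0]] = False
        return mask

    @cached_property
    def tip_indices(self) -> np.ndarray:
        mask = np.ones(self.parent.size, dtype=bool)
        mask[self.parent[self.parent >= 0]] = False
        return np.flatnonzero(mask)

    @cached_property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @cached_property
    def tip_index_of(self) -> dict[str, int]:
        """Map tip label -> node index."""
        return {self.labels[i]: int(i) for i in self.tip_indices}

    @cached_property
    def n_tips(self) -> int:
        return int(self.tip_indices.size)

    @cached_property
    def subtree_tip_counts(self) -> np.ndarray:
        """Number of tips descending from each node (tips count themselves)."""
        counts = self.is_tip.astype(np.int64)
        for i in range(self.n_nodes - 1, 0, -1):  # reversed preorder = postorder
            counts[self.parent[i]] += counts[i]
        return counts

    # ------------------------------------------------------------- operations
    def total_branch_length(self) -> float:
        """Sum of all edge lengths (any root edge excluded)."""
        return float(self.length.sum())

    def with_lengths(self, new_lengths: np.ndarray) -> "PhyloTree":
        """Same topology and labels with replacement edge lengths."""
        return PhyloTree(self.parent, new_lengths, self.labels, self.rooted)

    def node_depths(self) -> np.ndarray:
        """Path length from the root to each node."""
        depth = np.zeros(self.n_nodes)
        for i in range(1, self.n_nodes):
            depth[i] = depth[self.parent[i]] + self.length[i]
        return depth

    def tip_paths(self) -> list[np.ndarray]:
        """For each tip (in ``tip_indices`` order) the node indices on its
        root-to-tip path, root excluded."""
        paths = []
        for t in self.tip_indices:
            path = []
            i = int(t)
            while i != 0:
                path.append(i)
                i = int(self.parent[i])
            paths.append(np.array(path[::-1], dtype=np.int64))
        return paths

    def patristic_distances(self, labels: Sequence[str] | None = None) -> pd.DataFrame:
        """Pairwise path-length distances between tips."""
        depth = self.node_depths()
        tips = [self.tip_index_of[l] for l in labels] if labels else list(self.tip_indices)
        names = [self.labels[i] for i in tips]
        # LCA via path sets; fine at the sizes this is used for (tests, checks)
        paths = {}
        for t in tips:
            anc = []
            i = t
            while i != -1:
                anc.append(i)
                i = int(self.parent[i])
            paths[t] = anc
        out = np.zeros((len(tips), len(tips)))
        for a, ta in enumerate(tips):
            seen = {node: k for k, node in enumerate(paths[ta])}
            for b in range(a + 1, len(tips)):
                tb = tips[b]
                for node in paths[tb]:
                    if node in seen:
                        lca = node
                        break
                d = depth[ta] + depth[tb] - 2 * depth[lca]
                out[a, b] = out[b, a] = d
        return pd.DataFrame(out, index=names, columns=names)

    def edge_table(self) -> pd.DataFrame:
        """Delimited-text-friendly edge list (root pseudo-edge excluded)."""
        child = np.arange(1, self.n_nodes)
        return pd.DataFrame({
            "parent_id": self.parent[child],
            "child_id": child,
            "length": self.length[child],
            "tip_label": [self.labels[i] if self.is_tip[i] else "" for i in child],
        })

    # ---------------------------------------------------------------- newick
    @classmethod
    def from_dendropy(cls, dtree: dendropy.Tree, rooted: bool = True) -> "PhyloTree":
        parent, length, labels = [], [], []
        index = {}
        for node in dtree.preorder_node_iter():
            i = len(parent)
            index[node] = i
            parent.append(index[node.parent_node] if node.parent_node else -1)
            length.append(node.edge.length if node.edge.length is not None else 0.0)
            if node.is_leaf():
                labels.append(node.taxon.label if node.taxon else node.label)
            else:
                labels.append(node.label)
        return cls(parent, length, labels, rooted=rooted)

    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        dtree = dendropy.Tree(taxon_namespace=taxa)
        nodes = [dtree.seed_node]
        nodes[0].edge.length = None
        for i in range(1, self.n_nodes):
            node = nodes[self.parent[i]].new_child(edge_length=float(self.length[i]))
            nodes.append(node)
        for i, node in enumerate(nodes):
            if self.is_tip[i]:
                node.taxon = taxa.new_taxon(self.labels[i])
            elif self.labels[i]:
                node.label = self.labels[i]
        dtree.is_rooted = self.rooted
        return dtree

    def to_newick(self) -> str:
        s = self.to_dendropy().as_string(
            schema="newick",
            suppress_rooting=True,
            unquoted_underscores=True,
            real_value_format_specifier=".10g",
        ).strip()
        return s

    def rerooted_at(self, node_index: int) -> "PhyloTree":
        """Reroot at an existing internal node (edge set unchanged)."""
        dtree = self.to_dendropy()
        nodes = list(dtree.preorder_node_iter())
        dtree.reroot_at_node(nodes[node_index], update_bipartitions=False)
        return PhyloTree.from_dendropy(dtree, rooted=self.rooted)

    # ----------------------------------------------------------------- dunder
    def __eq__(self, other) -> bool:
        if not isinstance(other, PhyloTree):
            return NotImplemented
        return (self.labels == other.labels
                and np.array_equal(self.parent, other.parent)
                and np.allclose(self.length, other.length, rtol=1e-9, atol=1e-300))

    def __repr__(self) -> str:
        kind = "rooted" if self.rooted else "unrooted"
        return f"<PhyloTree {kind}, {self.n_tips} tips, {self.n_nodes} nodes>"


def _check_parentheses(text: str) -> None:
    depth = 0
    for offset, ch in enumerate(text):
        if ch == "(":
            depth += 1
        elif ch == ")":
            depth -= 1
            if depth < 0:
                raise NewickParseError(
                    f"unbalanced ')' at character offset {offset}")
    if depth != 0:
        raise NewickParseError(
            f"{depth} unclosed '(' by character offset {len(text)}")


def read_newick(text: str, rooted: bool = True) -> PhyloTree:
    """Parse a Newick string (branch lengths optional, missing read as 0)."""
    _check_parentheses(text)
    try:
        dtree = dendropy.Tree.get(data=text, schema="newick",
                                  suppress_internal_node_taxa=True,
                                  preserve_underscores=True)
    except Exception as exc:  # dendropy raises several error classes
        if "Duplicate taxon labels" in str(exc):
            raise TreeValidationError(f"duplicate tip labels: {exc}") from exc
        raise NewickParseError(f"malformed Newick: {exc}") from exc
    return PhyloTree.from_dendropy(dtree, rooted=rooted)


def write_newick(tree: PhyloTree) -> str:
    return tree.to_newick()


def total_branch_length(tree: PhyloTree) -> float:
    """Phylogenetic diversity of the whole tree: the sum of all branch lengths."""
    return tree.total_branch_length()
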