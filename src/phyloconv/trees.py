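"""Array-backed rooted phylogeny used throughout the pipeline.

Newick parsing/writing is delegated to dendropy; this class flattens the
tree into parent/child integer arrays so that pruning and simulation can be
vectorised.  Branches are identified by their child node, and every node
carries a label (tip labels from the input, internal labels auto-generated
as ``N<postorder index>`` when absent).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import dendropy
import numpy as np

logger = logging.getLogger(__name__)

#: Branch lengths of exactly zero (or absent) are replaced by this value so
#: that transition probabilities stay well-defined.
DEFAULT_BRANCH_EPSILON = 1e-6


class TreeFormatError(ValueError):
    """Raised for trees the pipeline cannot use (duplicate tips, no root...)."""


@dataclass
class Phylogeny:
    """Rooted phylogeny with positive branch lengths.

    Nodes are indexed ``0..n_nodes-1`` in postorder, so the root is always
    the last index and every child index is smaller than its parent's.

    Attributes
    ----------
    parent:
        Parent index per node; ``-1`` for the root.
    blen:
        Branch length of the edge above each node; 0.0 for the root.
    labels:
        Node labels; unique across the tree.
    n_tips:
        Number of leaves.  Leaves occupy the indices for which
        ``is_tip`` is True (not necessarily ``0..n_tips-1``).
    """

    parent: np.ndarray
    blen: np.ndarray
    labels: list[str]
    is_tip: np.ndarray
    children: list[list[int]] = field(repr=False)

    def __post_init__(self) -> None:
        self.n_nodes = len(self.parent)
        self.n_tips = int(self.is_tip.sum())
        self.root = self.n_nodes - 1
        self.label_to_index = {lab: i for i, lab in enumerate(self.labels)}
        if len(self.label_to_index) != self.n_nodes:
            raise TreeFormatError("node labels are not unique")

    # ------------------------------------------------------------------
    # construction
    # ------------------------------------------------------------------
    @classmethod
    def from_dendropy(
        cls, tree: dendropy.Tree, epsilon: float = DEFAULT_BRANCH_EPSILON
    ) -> "Phylogeny":
        root = tree.seed_node
        if len(root.child_nodes()) != 2:
            raise TreeFormatError(
                "tree root is not bifurcating; root the tree (e.g. on an "
                "outgroup or at the midpoint) before loading"
            )
        nodes = list(tree.postorder_node_iter())
        index = {id(nd): i for i, nd in enumerate(nodes)}
        n = len(nodes)
        parent = np.full(n, -1, dtype=np.int64)
        blen = np.zeros(n, dtype=float)
        is_tip = np.zeros(n, dtype=bool)
        labels: list[str] = []
        children: list[list[int]] = [[] for _ in range(n)]
        seen: set[str] = set()
        n_epsilon = 0
        for i, nd in enumerate(nodes):
            if nd.parent_node is not None:
                parent[i] = index[id(nd.parent_node)]
                children[parent[i]].append(i)
                length = nd.edge.length
                if length is None or length <= 0.0:
                    length = epsilon
                    n_epsilon += 1
                blen[i] = length
            if nd.is_leaf():
                is_tip[i] = True
                if nd.taxon is None or not nd.taxon.label:
                    raise TreeFormatError("tip without a label")
                lab = nd.taxon.label
            else:
                lab = nd.label if nd.label else f"N{i}"
            if lab in seen:
                raise TreeFormatError(f"duplicate node label: {lab!r}")
            seen.add(lab)
            labels.append(lab)
        if n_epsilon:
            logger.warning(
                "replaced %d zero/absent branch lengths by epsilon=%g",
                n_epsilon,
                epsilon,
            )
        return cls(parent=parent, blen=blen, labels=labels, is_tip=is_tip, children=children)

    @classmethod
    def from_newick(
        cls, newick: str, epsilon: float = DEFAULT_BRANCH_EPSILON
    ) -> "Phylogeny":
        try:
            tree = dendropy.Tree.get(
                data=newick, schema="newick", preserve_underscores=True
            )
        except dendropy.utility.error.DataParseError as err:
            raise TreeFormatError(str(err)) from err
        return cls.from_dendropy(tree, epsilon=epsilon)

    # ------------------------------------------------------------------
    # views
    # ------------------------------------------------------------------
    @property
    def tip_indices(self) -> np.ndarray:
        return np.flatnonzero(self.is_tip)

    @property
    def tip_labels(self) -> list[str]:
        return [self.labels[i] for i in self.tip_indices]

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    def postorder(self) -> np.ndarray:
        """Node indices in postorder (children before parents)."""
        return np.arange(self.n_nodes)

    def preorder(self) -> np.ndarray:
        """Node indices in preorder (parents before children)."""
        return np.arange(self.n_nodes)[::-1]

    def branch_nodes(self) -> np.ndarray:
        """Child-node index of every branch, in preorder."""
        return np.array([i for i in self.preorder() if i != self.root])

    def subtree(self, node: int) -> np.ndarray:
        """All node indices in the clade rooted at ``node`` (inclusive)."""
        out = [node]
        stack = [node]
        while stack:
            for c in self.children[stack.pop()]:
                out.append(c)
                stack.append(c)
        return np.array(sorted(out))

    def total_length(self) -> float:
        return float(self.blen.sum())

    # ------------------------------------------------------------------
    # export
    # ------------------------------------------------------------------
    def to_dendropy(self) -> dendropy.Tree:
        taxa = dendropy.TaxonNamespace()
        tree = dendropy.Tree(taxon_namespace=taxa)
        dnodes = [None] * self.n_nodes
        for i in reversed(range(self.n_nodes)):  # preorder
            nd = dendropy.Node()
            if self.is_tip[i]:
                nd.taxon = taxa.new_taxon(label=self.labels[i])
            else:
                nd.label = self.labels[i]
            if self.parent[i] >= 0:
                nd.edge.length = float(self.blen[i])
                dnodes[self.parent[i]].add_child(nd)
            else:
                tree.seed_node = nd
            dnodes[i] = nd
        tree.is_rooted = True
        return tree

    def to_newick(self) -> str:
        return self.to_dendropy().as_string(
            schema="newick", suppress_rooting=True, unquoted_underscores=True
        ).strip()
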