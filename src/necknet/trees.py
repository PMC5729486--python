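"""Calibrated phylogenies: parsing, covariance matrices and tree traversals.

Wraps :mod:`dendropy` trees with the quantities the comparative methods
need: the Brownian-motion variance-covariance matrix implied by shared
branch lengths, node heights and subclade tip sets (for disparity through
time), and the Abouheif phylogenetic proximity matrix.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import dendropy
import numpy as np

__all__ = ["PhyloTree", "NodeRecord"]


@dataclass(frozen=True)
class NodeRecord:
    """Per-node summary used by traversal-based analyses."""

    height: float  # time from the root
    parent_height: float  # height of the parent (root: 0.0)
    tips: frozenset  # labels of descendant tips
    is_leaf: bool


class PhyloTree:
    """A rooted, branch-lengthed phylogeny with named tips."""

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        labels = [leaf.taxon.label for leaf in tree.leaf_node_iter()]
        if len(set(labels)) != len(labels):
            raise ValueError("tip names are not unique")
        for edge in tree.preorder_edge_iter():
            if edge.head_node is not tree.seed_node and edge.length is None:
                raise ValueError("tree has missing branch lengths")
        self.tip_labels: list[str] = labels
        tree.calc_node_root_distances(
            return_leaf_distances_only=False
        )

    # -- construction -----------------------------------------------------

    @classmethod
    def from_newick(cls, text: str) -> "PhyloTree":
        tree = dendropy.Tree.get(
            data=text, schema="newick", preserve_underscores=True
        )
        return cls(tree)

    def to_newick(self) -> str:
        return self._tree.as_string(schema="newick", unquoted_underscores=True)

    @property
    def dendropy_tree(self) -> dendropy.Tree:
        return self._tree

    @property
    def n_tips(self) -> int:
        return len(self.tip_labels)

    # -- basic geometry ----------------------------------------------------

    @property
    def depth(self) -> float:
        """Maximum root-to-tip distance (the root age for ultrametric trees)."""
        return max(
            leaf.root_distance for leaf in self._tree.leaf_node_iter()
        )

    def is_ultrametric(self, rtol: float = 1e-6) -> bool:
        depths = np.array(
            [leaf.root_distance for leaf in self._tree.leaf_node_iter()]
        )
        return bool(np.all(np.abs(depths - depths.max()) <= rtol * depths.max()))

    def check_tips(self, species: Sequence[str]) -> dict[str, list[str]]:
        """Cross-check tip names against a species list.

        Returns ``{"missing_in_tree": [...], "missing_in_data": [...]}``.
        """
        tips = set(self.tip_labels)
        data = set(species)
        return {
            "missing_in_tree": sorted(data - tips),
            "missing_in_data": sorted(tips - data),
        }

    # -- covariance --------------------------------------------------------

    def vcv(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Brownian-motion covariance matrix of the tips.

        ``C[i, j]`` is the root-to-MRCA distance of tips *i* and *j* (their
        shared evolutionary time); the diagonal holds root-to-tip distances.
        ``order`` fixes the row/column ordering (default: tree tip order).
        """
        order = list(order) if order is not None else self.tip_labels
        idx = {lbl: i for i, lbl in enumerate(order)}
        missing = set(order) - set(self.tip_labels)
        if missing:
            raise ValueError(f"species not in tree: {sorted(missing)}")
        n = len(order)
        C = np.zeros((n, n))
        tipsets: dict[int, list[int]] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                if node.taxon.label in idx:
                    i = idx[node.taxon.label]
                    tipsets[id(node)] = [i]
                    C[i, i] = node.root_distance
                else:
                    tipsets[id(node)] = []
            else:
                child_sets = [tipsets.pop(id(c)) for c in node.child_nodes()]
                h = node.root_distance or 0.0
                for a in range(len(child_sets)):
                    for b in range(a + 1, len(child_sets)):
                        for i in child_sets[a]:
                            for j in child_sets[b]:
                                C[i, j] = C[j, i] = h
                merged = [i for s in child_sets for i in s]
                tipsets[id(node)] = merged
        return C

    # -- traversal records ---------------------------------------------------

    def node_table(self) -> list[NodeRecord]:
        """All nodes (root excluded from 'leaf' logic) with heights and tip sets."""
        records = []
        tipsets: dict[int, frozenset] = {}
        for node in self._tree.postorder_node_iter():
            if node.is_leaf():
                tips = frozenset([node.taxon.label])
            else:
                tips = frozenset().union(
                    *(tipsets[id(c)] for c in node.child_nodes())
                )
            tipsets[id(node)] = tips
            parent = node.parent_node
            records.append(
                NodeRecord(
                    height=float(node.root_distance or 0.0),
                    parent_height=float(parent.root_distance or 0.0)
                    if parent is not None
                    else 0.0,
                    tips=tips,
                    is_leaf=node.is_leaf(),
                )
            )
        return records

    # -- Abouheif proximity --------------------------------------------------

    def abouheif_proximity(self, order: Sequence[str] | None = None) -> np.ndarray:
        """Abouheif's phylogenetic proximity matrix ('oriented' construction).

        For tips *i* != *j* the proximity is the product of 1/(number of
        direct descendants) over every internal node on the path from *i*
        to *j* (the MRCA counted once); the diagonal is zero.  Branch
        lengths do not enter: the matrix depends on topology only.
        """
        order = list(order) if order is not None else self.tip_labels
        idx = {lbl: i for i, lbl in enumerate(order)}
        n = len(order)
        # ancestor chains (bottom-up) for each tip
        chains: dict[int, list] = {}
        dd: dict[int, int] = {}
        for node in self._tree.preorder_node_iter():
            if not node.is_leaf():
                dd[id(node)] = len(node.child_nodes())
        for leaf in self._tree.leaf_node_iter():
            if leaf.taxon.label not in idx:
                continue
            chain = []
            p = leaf.parent_node
            while p is not None:
                chain.append(id(p))
                p = p.parent_node
            chains[idx[leaf.taxon.label]] = chain
        A = np.zeros((n, n))
        for i in range(n):
            anc_i = chains[i]
            pos_i = {nid: k for k, nid in enumerate(anc_i)}
            for j in range(i + 1, n):
                anc_j = chains[j]
                for kj, nid in enumerate(anc_j):
                    if nid in pos_i:
                        ki = pos_i[nid]
                        break
                path_nodes = anc_i[: ki + 1] + anc_j[:kj]
                prox = 1.0
                for nid2 in path_nodes:
                    prox /= dd[nid2]
                A[i, j] = A[j, i] = prox
        return A
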