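"""Phylogeny handling: Newick parsing, foreground-branch marks, tree indexing.

Foreground branches for branch-site analysis are marked in Newick with the
conventional ``#1`` label suffix on a leaf or internal-node label, e.g.
``((A,B)#1,C,D);`` marks the stem branch of the (A,B) clade.  At most one
mark is allowed per analysis.

Trees parsed here are also flattened into a postorder array form
(:class:`TreeIndex`) consumed by the likelihood engine and the simulator.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import dendropy
import numpy as np

_MARK_RE = re.compile(r"\s*#\s*(\d+)\s*$")


class TreeError(ValueError):
    pass


@dataclass
class TreeNode:
    label: str | None
    length: float
    children: list["TreeNode"] = field(default_factory=list)
    foreground: bool = False  # mark on the branch above this node

    @property
    def is_leaf(self) -> bool:
        return not self.children


class Phylogeny:
    """Rooted-or-unrooted tree with branch lengths and one optional mark."""

    def __init__(self, root: TreeNode):
        self.root = root
        marks = [n for n in self.postorder() if n.foreground]
        if len(marks) > 1:
            raise TreeError("at most one foreground mark is allowed")
        if marks and marks[0] is root:
            raise TreeError("foreground mark on the root has no branch")
        for n in self.postorder():
            if n.length < 0:
                raise TreeError(f"negative branch length at {n.label}")
        labels = self.leaf_labels()
        if len(set(labels)) != len(labels):
            raise TreeError("duplicate leaf labels")

    # -- construction ------------------------------------------------------
    @classmethod
    def from_newick(cls, newick: str) -> "Phylogeny":
        tree = dendropy.Tree.get(
            data=newick,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
        )
        return cls(cls._convert(tree.seed_node))

    @classmethod
    def from_file(cls, path) -> "Phylogeny":
        with open(path) as fh:
            return cls.from_newick(fh.read())

    @staticmethod
    def _convert(dnode) -> TreeNode:
        raw = None
        if dnode.taxon is not None:
            raw = dnode.taxon.label
        elif dnode.label is not None:
            raw = dnode.label
        fg = False
        if raw is not None:
            m = _MARK_RE.search(raw)
            if m:
                if m.group(1) != "1":
                    raise TreeError(f"unsupported mark #{m.group(1)} (only #1)")
                fg = True
                raw = raw[: m.start()].strip() or None
        node = TreeNode(
            label=raw,
            length=dnode.edge.length if dnode.edge.length is not None else 0.0,
            foreground=fg,
        )
        node.children = [Phylogeny._convert(c) for c in dnode.child_nodes()]
        return node

    # -- traversal ---------------------------------------------------------
    def postorder(self):
        def walk(n):
            for c in n.children:
                yield from walk(c)
            yield n

        yield from walk(self.root)

    def leaves(self) -> list[TreeNode]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def foreground_node(self) -> TreeNode | None:
        for n in self.postorder():
            if n.foreground:
                return n
        return None

    def clade_leaves(self, node: TreeNode) -> set[str]:
        return {leaf.label for leaf in (n for n in self._subtree(node)) if leaf.is_leaf}

    @staticmethod
    def _subtree(node: TreeNode):
        yield node
        for c in node.children:
            yield from Phylogeny._subtree(c)

    def mrca(self, taxa: set[str]) -> TreeNode:
        """Smallest clade (under the current rooting) containing all taxa."""
        target = set(taxa)
        best = None
        for n in self.postorder():
            if n.is_leaf:
                n._below = {n.label}
            else:
                n._below = set().union(*(c._below for c in n.children))
            if target <= n._below and (best is None or len(n._below) < len(best._below)):
                best = n
        if best is None:
            raise TreeError(f"taxa {sorted(target)} not all present in tree")
        return best

    def is_monophyletic(self, taxa: set[str]) -> bool:
        return self.clade_leaves(self.mrca(set(taxa))) == set(taxa)

    def mark_clade(self, taxa: set[str]) -> None:
        """Place the single foreground mark on the stem branch of a clade."""
        for n in self.postorder():
            n.foreground = False
        node = self.mrca(set(taxa))
        if self.clade_leaves(node) != set(taxa):
            raise TreeError(f"taxa {sorted(taxa)} are not monophyletic here")
        if node is self.root:
            raise TreeError("cannot mark the root branch")
        node.foreground = True

    # -- serialization -----------------------------------------------------
    def to_newick(self) -> str:
        def fmt(n: TreeNode) -> str:
            label = n.label or ""
            if n.foreground:
                label += "#1"
            if n.is_leaf:
                body = label
            else:
                body = "(" + ",".join(fmt(c) for c in n.children) + ")" + label
            return f"{body}:{n.length:.10g}" if n is not self.root else body

        return fmt(self.root) + ";"

    def copy(self) -> "Phylogeny":
        return Phylogeny.from_newick(self.to_newick())

    def to_index(self, taxa_order: list[str]) -> "TreeIndex":
        return TreeIndex.from_phylogeny(self, taxa_order)


@dataclass
class TreeIndex:
    """Array form of a tree for vectorized pruning.

    Nodes are numbered in postorder with the root last.  ``parent[i]`` is
    the postorder index of node i's parent (-1 for root); ``tip_taxon[i]``
    maps leaf nodes to rows of the alignment (-1 for internal nodes).
    """

    parent: np.ndarray
    lengths: np.ndarray
    tip_taxon: np.ndarray
    foreground: np.ndarray  # bool per node: branch above node is foreground
    children: list[list[int]]
    labels: list[str | None]

    @property
    def n_nodes(self) -> int:
        return len(self.parent)

    @property
    def root(self) -> int:
        return self.n_nodes - 1

    @property
    def n_branches(self) -> int:
        return self.n_nodes - 1

    @classmethod
    def from_phylogeny(cls, phylo: Phylogeny, taxa_order: list[str]) -> "TreeIndex":
        nodes = list(phylo.postorder())
        index = {id(n): i for i, n in enumerate(nodes)}
        tree_taxa = set(phylo.leaf_labels())
        if tree_taxa != set(taxa_order):
            raise TreeError(
                "tree/alignment taxon mismatch: "
                f"only in tree {sorted(tree_taxa - set(taxa_order))}, "
                f"only in alignment {sorted(set(taxa_order) - tree_taxa)}"
            )
        parent = np.full(len(nodes), -1, dtype=int)
        lengths = np.zeros(len(nodes))
        tip = np.full(len(nodes), -1, dtype=int)
        fg = np.zeros(len(nodes), dtype=bool)
        children: list[list[int]] = [[] for _ in nodes]
        for i, n in enumerate(nodes):
            lengths[i] = n.length
            fg[i] = n.foreground
            if n.is_leaf:
                tip[i] = taxa_order.index(n.label)
            for c in n.children:
                parent[index[id(c)]] = i
                children[i].append(index[id(c)])
        return cls(parent, lengths, tip, fg, children, [n.label for n in nodes])
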