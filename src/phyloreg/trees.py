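"""Rooted binary phylogenies: parsing, traversal, and leaf distances.

Newick parsing is delegated to :mod:`dendropy`; the parsed tree is converted
into a small node structure that the dynamic-programming recursions
(ancestral reconstruction, history inference) walk directly.
"""
from __future__ import annotations

from typing import Iterator

import dendropy
import numpy as np

__all__ = [
    "TreeNode",
    "Phylogeny",
    "NewickFormatError",
    "NonBinaryTreeError",
    "read_newick",
    "leaf_distance",
    "random_binary_tree",
]


class NewickFormatError(ValueError):
    """Raised when a newick string cannot be parsed."""


class NonBinaryTreeError(ValueError):
    """Raised when a tree is not strictly binary and auto-resolve is off."""


class TreeNode:
    """A node of a rooted phylogeny.

    Attributes
    ----------
    label : str
        Leaf labels come from the newick string; unlabeled internal nodes
        are named ``N1, N2, ...`` in preorder.
    length : float
        Branch length to the parent (1.0 when the newick omits it; the
        root's length is 0.0).
    """

    __slots__ = ("label", "length", "parent", "children")

    def __init__(self, label: str = "", length: float = 1.0):
        self.label = label
        self.length = float(length)
        self.parent: TreeNode | None = None
        self.children: list[TreeNode] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "TreeNode") -> "TreeNode":
        child.parent = self
        self.children.append(child)
        return child

    def __repr__(self) -> str:  # pragma: no cover
        return f"TreeNode({self.label!r})"


class Phylogeny:
    """A rooted, strictly binary phylogeny with uniquely labeled leaves."""

    def __init__(self, root: TreeNode):
        self.root = root
        self._index: dict[str, TreeNode] = {}
        self._label_nodes()
        self._validate()

    # -- construction helpers -------------------------------------------------

    def _label_nodes(self) -> None:
        counter = 1
        for node in self.preorder():
            if not node.label:
                while f"N{counter}" in self._index:
                    counter += 1
                node.label = f"N{counter}"
                counter += 1
            if node.label in self._index:
                raise ValueError(f"duplicate node label {node.label!r}")
            self._index[node.label] = node
        self.root.length = 0.0

    def _validate(self) -> None:
        for node in self.preorder():
            if node.children and len(node.children) != 2:
                raise NonBinaryTreeError(
                    f"node {node.label!r} has {len(node.children)} children; "
                    "the tree must be strictly binary (use auto_resolve)"
                )

    # -- traversal ------------------------------------------------------------

    def preorder(self) -> Iterator[TreeNode]:
        stack = [self.root]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator[TreeNode]:
        out: list[TreeNode] = []
        stack = [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        return iter(reversed(out))

    @property
    def leaves(self) -> list[TreeNode]:
        return [n for n in self.preorder() if n.is_leaf]

    @property
    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves]

    @property
    def internal_nodes(self) -> list[TreeNode]:
        return [n for n in self.preorder() if not n.is_leaf]

    @property
    def n_leaves(self) -> int:
        return len(self.leaves)

    @property
    def n_nodes(self) -> int:
        return sum(1 for _ in self.preorder())

    def node(self, label: str) -> TreeNode:
        try:
            return self._index[label]
        except KeyError:
            raise KeyError(f"unknown node label {label!r}") from None

    def branches(self) -> list[tuple[TreeNode, TreeNode]]:
        """All (parent, child) pairs, in preorder of the child."""
        return [(n.parent, n) for n in self.preorder() if n.parent is not None]

    # -- metrics --------------------------------------------------------------

    def depth(self, node: TreeNode) -> float:
        d = 0.0
        while node.parent is not None:
            d += node.length
            node = node.parent
        return d

    def leaf_distance(self, a: str, b: str) -> float:
        """Sum of branch lengths on the path between two leaves."""
        na, nb = self.node(a), self.node(b)
        if not na.is_leaf or not nb.is_leaf:
            raise ValueError("leaf_distance arguments must be leaves")
        ancestors = {}
        d, node = 0.0, na
        while node is not None:
            ancestors[id(node)] = d
            d += node.length
            node = node.parent
        d, node = 0.0, nb
        while id(node) not in ancestors:
            d += node.length
            node = node.parent
        return d + ancestors[id(node)]

    def leaf_distance_matrix(self) -> tuple[list[str], np.ndarray]:
        labels = self.leaf_labels
        n = len(labels)
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j] = D[j, i] = self.leaf_distance(labels[i], labels[j])
        return labels, D

    # -- serialization --------------------------------------------------------

    def to_newick(self) -> str:
        def fmt(node: TreeNode) -> str:
            if node.is_leaf:
                core = node.label
            else:
                core = "(" + ",".join(fmt(c) for c in node.children) + ")" + node.label
            if node.parent is not None:
                core += f":{node.length:g}"
            return core

        return fmt(self.root) + ";"

    def __repr__(self) -> str:  # pragma: no cover
        return f"Phylogeny({self.n_leaves} leaves, {self.n_nodes} nodes)"


def read_newick(text: str, auto_resolve: bool = False) -> Phylogeny:
    """Parse a newick string into a rooted binary :class:`Phylogeny`.

    Parameters
    ----------
    text:
        A newick tree description. Branch lengths are preserved when
        present and default to 1.0 otherwise.
    auto_resolve:
        When True, multifurcations are resolved arbitrarily with
        zero-length branches instead of raising ``NonBinaryTreeError``.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text, schema="newick", suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several error types
        offset = getattr(exc, "col_num", None)
        where = f" near character {offset}" if offset is not None else ""
        raise NewickFormatError(f"invalid newick{where}: {exc}") from exc
    if auto_resolve:
        dtree.resolve_polytomies()

    def convert(dnode) -> TreeNode:
        if dnode.taxon is not None:
            label = dnode.taxon.label
        else:
            label = dnode.label or ""
        length = dnode.edge.length if dnode.edge.length is not None else 1.0
        node = TreeNode(label=label, length=length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    return Phylogeny(convert(dtree.seed_node))


def leaf_distance(tree: Phylogeny, a: str, b: str) -> float:
    """Module-level convenience wrapper for :meth:`Phylogeny.leaf_distance`."""
    return tree.leaf_distance(a, b)


def random_binary_tree(
    n_leaves: int,
    seed: int | np.random.Generator | None = None,
    branch_length: float = 1.0,
) -> Phylogeny:
    """Grow a random rooted binary tree by repeatedly splitting a random leaf.

    With ``n_leaves`` leaves the tree has ``2 * n_leaves - 1`` nodes. Leaves
    are labeled ``L01, L02, ...`` in preorder at the end, so the labeling is
    reproducible for a fixed seed.
    """
    if n_leaves < 2:
        raise ValueError("need at least 2 leaves")
    rng = np.random.default_rng(seed)
    root = TreeNode()
    leaves = [root.add_child(TreeNode(length=branch_length)) for _ in range(2)]
    while len(leaves) < n_leaves:
        victim = leaves.pop(int(rng.integers(len(leaves))))
        leaves.extend(
            victim.add_child(TreeNode(length=branch_length)) for _ in range(2)
        )
    tree = Phylogeny(root)
    width = len(str(n_leaves))
    for i, leaf in enumerate(tree.leaves, start=1):
        del tree._index[leaf.label]
        leaf.label = f"L{i:0{width}d}"
        tree._index[leaf.label] = leaf
    return tree
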