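"""Unrooted binary trees with branch lengths.

Internally a tree is stored rooted at an arbitrary internal node of degree 3
(degree 2 only for the trivial two-leaf tree); under time-reversible models
the likelihood does not depend on this rooting.  Branch lengths are expected
substitutions per site and live on the child end of each edge.
"""

from __future__ import annotations

import io as _io

import dendropy

from .errors import TreeError

BL_MIN = 1e-8
BL_MAX = 10.0


class Node:
    __slots__ = ("label", "length", "children", "parent")

    def __init__(self, label=None, length=None):
        self.label = label
        self.length = length  # length of the edge to the parent; None at root
        self.children: list[Node] = []
        self.parent: Node | None = None

    def add_child(self, node: "Node") -> "Node":
        node.parent = self
        self.children.append(node)
        return node

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def __repr__(self):  # pragma: no cover - debugging aid
        kind = f"leaf {self.label!r}" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {kind} len={self.length}>"


class Tree:
    def __init__(self, root: Node):
        self.root = root

    # ---------------------------------------------------------------- basics

    def postorder(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(node.children)
        out.reverse()
        return out

    def preorder(self) -> list[Node]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            out.append(node)
            stack.extend(reversed(node.children))
        return out

    def leaves(self) -> list[Node]:
        return [n for n in self.postorder() if n.is_leaf]

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    def edges(self) -> list[Node]:
        """Every edge, identified by its child node (root excluded)."""
        return [n for n in self.postorder() if n.parent is not None]

    def internal_edges(self) -> list[Node]:
        """Edges whose child end is an internal node."""
        return [n for n in self.edges() if not n.is_leaf]

    def n_leaves(self) -> int:
        return len(self.leaves())

    def find_leaf(self, label: str) -> Node:
        for n in self.postorder():
            if n.is_leaf and n.label == label:
                return n
        raise TreeError(f"no leaf labelled {label!r}")

    def copy(self) -> "Tree":
        def _copy(node):
            new = Node(node.label, node.length)
            for c in node.children:
                new.add_child(_copy(c))
            return new

        return Tree(_copy(self.root))

    def total_length(self) -> float:
        return sum(n.length or 0.0 for n in self.edges())

    # ------------------------------------------------------------- topology

    def _leafsets(self) -> dict:
        sets = {}
        for node in self.postorder():
            if node.is_leaf:
                sets[id(node)] = frozenset([node.label])
            else:
                sets[id(node)] = frozenset().union(
                    *(sets[id(c)] for c in node.children)
                )
        return sets

    def splits(self) -> set[frozenset]:
        """Canonical non-trivial splits (the side not containing the
        lexicographically smallest leaf label)."""
        all_leaves = frozenset(self.leaf_labels())
        ref = min(all_leaves)
        sets = self._leafsets()
        out = set()
        for node in self.edges():
            side = sets[id(node)]
            if ref in side:
                side = all_leaves - side
            if 2 <= len(side) <= len(all_leaves) - 2:
                out.add(side)
        return out

    def is_monophyletic(self, clade) -> bool:
        """True iff some branch separates exactly ``clade`` from the rest."""
        clade = frozenset(clade)
        all_leaves = frozenset(self.leaf_labels())
        if not clade < all_leaves or len(clade) < 1:
            raise TreeError("clade must be a proper subset of the leaf set")
        if len(clade) == 1 or len(clade) == len(all_leaves) - 1:
            return True  # trivial split always present in a binary tree
        sets = self._leafsets()
        for node in self.edges():
            side = sets[id(node)]
            if side == clade or side == all_leaves - clade:
                return True
        return False

    def same_topology(self, other: "Tree") -> bool:
        if set(self.leaf_labels()) != set(other.leaf_labels()):
            return False
        return self.splits() == other.splits()

    # ----------------------------------------------------------------- edit

    def unroot(self) -> "Tree":
        """Ensure the root has degree 3 (merging a basal bifurcation)."""
        root = self.root
        while len(root.children) == 2 and any(
            not c.is_leaf for c in root.children
        ):
            internal = next(c for c in root.children if not c.is_leaf)
            other = next(c for c in root.children if c is not internal)
            # fold `other` under `internal`; the two basal edges merge
            other.length = (other.length or 0.0) + (internal.length or 0.0)
            internal.parent = None
            internal.length = None
            internal.add_child(other)
            root = internal
        self.root = root
        return self

    def attach_leaf(
        self, edge_child: Node, label: str, pendant: float = 0.1, frac: float = 0.5
    ) -> Node:
        """Insert a new leaf on the edge above ``edge_child``.

        A new internal node is created at fraction ``frac`` of the edge
        (measured from the parent side); returns the new leaf node.
        """
        parent = edge_child.parent
        if parent is None:
            raise TreeError("cannot attach on the root")
        old_len = edge_child.length
        mid = Node(length=old_len * frac)
        idx = parent.children.index(edge_child)
        parent.children[idx] = mid
        mid.parent = parent
        mid.add_child(edge_child)
        edge_child.length = old_len * (1.0 - frac)
        leaf = Node(label=label, length=pendant)
        mid.add_child(leaf)
        return leaf

    def detach_leaf(self, label: str) -> None:
        """Remove a leaf and suppress the resulting degree-2 node."""
        leaf = self.find_leaf(label)
        parent = leaf.parent
        if parent is None:
            raise TreeError("cannot detach the root")
        parent.children.remove(leaf)
        if parent.parent is not None and len(parent.children) == 1:
            # splice parent out, merging branch lengths
            child = parent.children[0]
            child.length = (child.length or 0.0) + (parent.length or 0.0)
            gp = parent.parent
            gp.children[gp.children.index(parent)] = child
            child.parent = gp
        elif parent.parent is None and len(parent.children) == 2:
            self.unroot()

    def newick(self, precision: int = 10) -> str:
        def _fmt(node):
            if node.is_leaf:
                body = node.label
            else:
                body = "(" + ",".join(_fmt(c) for c in node.children) + ")"
            if node.length is not None:
                body += f":{node.length:.{precision}g}"
            return body

        return _fmt(self.root) + ";"


def tree_from_newick(text: str) -> Tree:
    """Parse a Newick string into an unrooted tree."""
    dt = dendropy.Tree.get(
        data=text, schema="newick", preserve_underscores=True
    )

    def _convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else None
        node = Node(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(_convert(child))
        return node

    root = _convert(dt.seed_node)
    root.length = None
    tree = Tree(root)
    labels = tree.leaf_labels()
    if len(labels) != len(set(labels)):
        raise TreeError("duplicate leaf labels in Newick input")
    if len(labels) >= 3:
        tree.unroot()
    return tree


def read_tree(path) -> Tree:
    with open(path) as fh:
        return tree_from_newick(fh.read())


def write_tree(tree: Tree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick() + "\n")


def validate_lengths(tree: Tree) -> None:
    for node in tree.edges():
        if node.length is None or not (0.0 <= node.length <= BL_MAX + 1e-9):
            raise TreeError(
                f"branch length {node.length!r} outside [0, {BL_MAX}]"
            )


def clamp_lengths(tree: Tree) -> Tree:
    for node in tree.edges():
        if node.length is None:
            node.length = BL_MIN
        node.length = min(max(node.length, BL_MIN), BL_MAX)
    return tree
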