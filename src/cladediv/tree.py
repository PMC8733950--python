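"""Rooted phylogenetic trees with branch lengths.

A :class:`PhyloTree` is the universe a clade-divergence analysis lives in: a
rooted tree whose every non-root edge carries a branch length in expected
substitutions per site. Leaf labels are required to be unique because clades
are designated by leaf names. Internal node labels are plain names (a support
value, if present in that position, is carried along as a label and never
interpreted).

Newick I/O is delegated to dendropy; the parsed tree is converted into a
minimal node structure that the pruning and distance code manipulates
directly. ``parse_newick(write_newick(t))`` reproduces topology, labels and
branch lengths exactly.
"""

from __future__ import annotations

import io
import logging
import re
from dataclasses import dataclass, field
from typing import Iterator

import dendropy

from .errors import (
    CladeSelectionError,
    NewickParseError,
    TreeValidationError,
    UnknownLeafError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "Node",
    "PhyloTree",
    "CladeRef",
    "parse_newick",
    "write_newick",
    "find_mrca",
    "distance_to_clade_root",
]


class Node:
    """One node of a rooted tree.

    ``length`` is the length of the edge into this node from its parent
    (``None`` only for the root). Children keep their input order.
    """

    __slots__ = ("label", "length", "parent", "children")

    def __init__(self, label: str | None = None, length: float | None = None):
        self.label = label
        self.length = length
        self.parent: Node | None = None
        self.children: list[Node] = []

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def add_child(self, child: "Node") -> "Node":
        child.parent = self
        self.children.append(child)
        return child

    def preorder(self) -> Iterator["Node"]:
        stack = [self]
        while stack:
            node = stack.pop()
            yield node
            stack.extend(reversed(node.children))

    def postorder(self) -> Iterator["Node"]:
        out = list(self.preorder())
        return iter(reversed(out))

    def leaves(self) -> list["Node"]:
        return [n for n in self.preorder() if n.is_leaf]

    def copy_subtree(self) -> "Node":
        """Deep copy of the subtree rooted here (parent of the copy is None)."""
        clone = Node(self.label, self.length)
        for child in self.children:
            clone.add_child(child.copy_subtree())
        return clone

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        kind = "leaf" if self.is_leaf else f"internal({len(self.children)})"
        return f"<Node {self.label!r} {kind} length={self.length}>"


class PhyloTree:
    """A validated rooted tree.

    Invariants enforced at construction: exactly one root, unique leaf
    labels, and a branch length on every non-root edge. Negative branch
    lengths (which neighbour-joining can produce) are accepted with a logged
    warning and enter all downstream samples unchanged; zero lengths are
    ordinary values.
    """

    def __init__(self, root: Node):
        self.root = root
        self._validate()

    def _validate(self) -> None:
        seen: set[str] = set()
        for node in self.root.preorder():
            if node.is_leaf:
                if not node.label:
                    raise TreeValidationError("leaf without a label")
                if node.label in seen:
                    raise TreeValidationError(
                        f"duplicate leaf label: {node.label!r}"
                    )
                seen.add(node.label)
            if node is not self.root:
                if node.length is None:
                    name = node.label or self._describe(node)
                    raise TreeValidationError(
                        f"missing branch length on edge into node {name!r}"
                    )
                if node.length < 0:
                    logger.warning(
                        "negative branch length %g on node %r kept as-is",
                        node.length,
                        node.label or self._describe(node),
                    )

    @staticmethod
    def _describe(node: Node) -> str:
        tips = [n.label for n in node.leaves()][:3]
        return "ancestor-of-(" + ",".join(str(t) for t in tips) + ")"

    # -- queries ---------------------------------------------------------

    def preorder(self) -> Iterator[Node]:
        return self.root.preorder()

    def leaves(self) -> list[Node]:
        return self.root.leaves()

    @property
    def leaf_map(self) -> dict[str, Node]:
        return {n.label: n for n in self.leaves()}

    def find_node(self, label: str) -> Node | None:
        """First node (preorder) whose label equals ``label``."""
        for node in self.preorder():
            if node.label == label:
                return node
        return None

    def mrca(self, leaf_names: set[str]) -> Node:
        return find_mrca(self, leaf_names)


@dataclass(frozen=True)
class CladeRef:
    """A designated clade: a node of ``tree`` together with its subtree.

    The subtree must contain at least two leaves — a single sequence has no
    within-clade divergence to measure.
    """

    tree: PhyloTree
    node: Node = field(repr=False)

    def __post_init__(self) -> None:
        if len(self.node.leaves()) < 2:
            raise CladeSelectionError(
                "clade must contain at least 2 leaves "
                f"(got {len(self.node.leaves())})"
            )

    def leaves(self) -> list[Node]:
        return self.node.leaves()

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.leaves()]

    @property
    def stem_length(self) -> float | None:
        """Length of the edge into the clade root, if the clade is not the
        whole tree."""
        return self.node.length if self.node.parent is not None else None


# -- Newick I/O ----------------------------------------------------------


def parse_newick(text: str) -> PhyloTree:
    """Parse a Newick string into a validated :class:`PhyloTree`.

    Standard dialect: parenthesised topology, ``:length`` on edges, ``;``
    terminator, single-quoted labels, ``[...]`` comments (stripped).
    Underscores in unquoted labels are preserved literally. Internal node
    labels are kept as names.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            preserve_underscores=True,
            suppress_internal_node_taxa=True,
            suppress_leaf_node_taxa=True,  # duplicate labels checked by us
        )
    except Exception as exc:  # dendropy raises several error classes
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        raise NewickParseError(f"malformed Newick: {exc}", line, col) from exc

    def convert(dnode) -> Node:
        label = dnode.taxon.label if dnode.taxon is not None else dnode.label
        node = Node(label=label, length=dnode.edge.length)
        for child in dnode.child_nodes():
            node.add_child(convert(child))
        return node

    root = convert(dtree.seed_node)
    return PhyloTree(root)


_UNQUOTED_SAFE = re.compile(r"^[^\s()\[\]':;,]+$")


def _format_label(label: str) -> str:
    if _UNQUOTED_SAFE.match(label):
        return label
    return "'" + label.replace("'", "''") + "'"


def _format_length(length: float | None) -> str:
    if length is None:
        return ""
    return f":{length!r}"


def write_newick(tree: PhyloTree) -> str:
    """Serialise a tree to Newick, preserving labels and full-precision
    lengths so that ``parse_newick`` round-trips exactly."""
    out = io.StringIO()

    def emit(node: Node) -> None:
        if node.children:
            out.write("(")
            for i, child in enumerate(node.children):
                if i:
                    out.write(",")
                emit(child)
            out.write(")")
        if node.label is not None:
            out.write(_format_label(node.label))
        out.write(_format_length(node.length))

    emit(tree.root)
    out.write(";")
    return out.getvalue()


# -- distances and MRCA --------------------------------------------------


def find_mrca(tree: PhyloTree, leaf_names: set[str]) -> Node:
    """Deepest node whose subtree contains every named leaf."""
    if not leaf_names:
        raise UnknownLeafError([])
    lmap = tree.leaf_map
    missing = set(leaf_names) - set(lmap)
    if missing:
        raise UnknownLeafError(missing)
    nodes = [lmap[name] for name in leaf_names]
    # ancestor chain of the first leaf, then intersect by walking the others up
    chain: list[Node] = []
    n: Node | None = nodes[0]
    while n is not None:
        chain.append(n)
        n = n.parent
    index = {id(node): depth for depth, node in enumerate(chain)}
    best = 0
    for other in nodes[1:]:
        n = other
        while id(n) not in index:
            n = n.parent
        best = max(best, index[id(n)])
    return chain[best]


def distance_to_clade_root(clade: CladeRef, leaf: Node | str) -> float:
    """Sum of branch lengths from the clade root down to ``leaf``."""
    if isinstance(leaf, str):
        node = clade.tree.leaf_map.get(leaf)
        if node is None:
            raise UnknownLeafError([leaf])
        leaf = node
    total = 0.0
    n = leaf
    while n is not clade.node:
        if n.parent is None:
            raise CladeSelectionError(
                f"leaf {leaf.label!r} is not inside the clade"
            )
        total += n.length
        n = n.parent
    return total
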