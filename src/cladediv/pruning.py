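"""Clade restriction with branch-length updating.

When the comparison is restricted to the species common to both clades, each
clade is pruned down to one representative leaf per common species. Pruning
must not distort the divergence signal, so its defining contract is that the
patristic distance between any two *kept* leaves is exactly what it was in
the unpruned tree: removed subtrees are simply cut off, and every internal
node left with a single child is suppressed by merging its two incident
edges into one whose length is the sum.

If the clade root itself ends up with a single surviving child, the result
is re-rooted at the deepest node ancestral to all kept leaves, so the output
never contains a unifurcation and "the edges inside the clade" stays
well-defined.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import CladeSelectionError, SampleSizeError
from .tree import CladeRef, Node, PhyloTree

__all__ = ["PrunedClade", "prune_to_leaves", "branch_lengths", "BranchLengthSample"]


@dataclass(frozen=True)
class BranchLengthSample:
    """Multiset of within-clade branch lengths, the input to the two-sample
    tests. Duplicate values are meaningful and retained."""

    values: tuple[float, ...]
    label: str = ""

    def __len__(self) -> int:
        return len(self.values)


@dataclass(frozen=True)
class PrunedClade:
    """A standalone subtree restricted to ``kept`` leaves.

    ``removed_length`` is the total branch length discarded by the pruning
    (for logging); merged edges keep their exact summed length, nothing is
    redistributed.
    """

    tree: PhyloTree
    kept: frozenset[str]
    removed_length: float
    # stem length of the original (unpruned) clade, carried through so the
    # include-stem option keeps meaning after pruning
    original_stem_length: float | None = None

    def leaf_labels(self) -> list[str]:
        return [n.label for n in self.tree.leaves()]


def _subtree_length(node: Node) -> float:
    return sum(n.length for n in node.preorder() if n is not node)


def prune_to_leaves(clade: CladeRef, keep: set[str]) -> PrunedClade:
    """Restrict ``clade`` to the leaves named in ``keep``.

    Raises if fewer than two leaves are kept (no within-clade divergence is
    definable) or if ``keep`` names leaves outside the clade.
    """
    clade_leaves = set(clade.leaf_labels())
    extra = set(keep) - clade_leaves
    if extra:
        raise CladeSelectionError(
            f"leaves not in clade: {', '.join(sorted(extra))}"
        )
    if len(keep) < 2:
        raise CladeSelectionError(
            f"need >= 2 kept leaves to measure divergence (got {len(keep)})"
        )

    root = clade.node.copy_subtree()
    root.parent = None
    original_total = _subtree_length(root)

    def prune(node: Node) -> Node | None:
        if node.is_leaf:
            return node if node.label in keep else None
        survivors = [c for c in (prune(child) for child in node.children) if c]
        if not survivors:
            return None
        if len(survivors) == 1:
            # suppress the unifurcation: child absorbs this node's edge
            child = survivors[0]
            if node.length is not None and child.length is not None:
                child.length += node.length
            child.parent = None
            return child
        node.children = []
        for child in survivors:
            node.add_child(child)
        return node

    new_root = prune(root)
    if new_root is None or new_root.is_leaf:  # cannot happen with |keep|>=2
        raise CladeSelectionError("pruning removed the whole clade")
    # the new root's accumulated stem-ward length is outside the clade
    new_root.length = None
    new_tree = PhyloTree(new_root)
    removed = original_total - _subtree_length(new_root)
    return PrunedClade(
        tree=new_tree,
        kept=frozenset(keep),
        removed_length=removed,
        original_stem_length=clade.stem_length,
    )


def branch_lengths(
    clade: CladeRef | PrunedClade, include_stem: bool = False
) -> BranchLengthSample:
    """All edge lengths strictly inside the clade subtree.

    The stem edge (into the clade root) represents divergence of the
    duplicate itself before any speciation, so it is excluded by default;
    ``include_stem=True`` adds it. For a pruned clade the stem of the
    *original* clade is used, since pruning consumes the stem-ward path.
    """
    if isinstance(clade, PrunedClade):
        root = clade.tree.root
        label = ""
        stem = clade.original_stem_length
    else:
        root = clade.node
        label = clade.node.label or ""
        stem = clade.stem_length
    values = [n.length for n in root.preorder() if n is not root]
    if include_stem and stem is not None:
        values.append(stem)
    if len(values) < 2:
        raise SampleSizeError(
            f"only {len(values)} branch length(s) in clade; need >= 2"
        )
    return BranchLengthSample(values=tuple(values), label=label)
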