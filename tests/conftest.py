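"""Shared fixtures and independent oracles.

The random-tree generator here is deliberately independent of the synthetic
module under test (plain recursive construction, no shared code paths), and
the patristic oracle walks explicit parent chains on the original tree so
pruning is checked against something that never touches the pruning code.
"""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import settings

from cladediv.tree import Node, PhyloTree

settings.register_profile("suite", deadline=None, derandomize=True)
settings.load_profile("suite")

MICRO_TREE = (
    "((g1_sp1:0.1,g1_sp2:0.2)cladeA:0.05,"
    "(g2_sp1:0.4,g2_sp2:0.6)cladeB:0.05)duplication;"
)


def random_tree(rng: np.random.Generator, n_leaves: int) -> PhyloTree:
    """Random rooted binary tree with uniform-random branch lengths and
    plain ``L<i>`` leaf labels."""
    nodes = [Node(label=f"L{i}", length=round(float(rng.uniform(0.01, 2.0)), 6))
             for i in range(n_leaves)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node(length=round(float(rng.uniform(0.01, 2.0)), 6))
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for k, n in enumerate(nodes) if k not in (i, j)]
        nodes.append(parent)
    nodes[0].length = None
    return PhyloTree(nodes[0])


def patristic_oracle(tree: PhyloTree, a: str, b: str) -> float:
    """Leaf-to-leaf distance by explicit parent-chain walk (quadratic,
    independent of any library traversal)."""
    lmap = tree.leaf_map
    na, nb = lmap[a], lmap[b]
    anc = {}
    d = 0.0
    n = na
    while n is not None:
        anc[id(n)] = d
        d += n.length or 0.0
        n = n.parent
    d = 0.0
    n = nb
    while id(n) not in anc:
        d += n.length
        n = n.parent
    return d + anc[id(n)]


def canonical_form(node: Node):
    """Order-insensitive (topology, label, length) form for isomorphism
    comparison."""
    if node.is_leaf:
        return ("leaf", node.label, node.length)
    kids = sorted(canonical_form(c) for c in node.children)
    return ("int", node.label, node.length, tuple(kids))


@pytest.fixture
def micro_tree():
    from cladediv import parse_newick

    return parse_newick(MICRO_TREE)
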