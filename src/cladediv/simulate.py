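"""Synthetic duplicated gene trees with known ground truth.

The generator emulates the situation the divergence test is built for: a
single gene duplication at the root splits the tree into two paralogous
clades, each containing one gene copy per species. One random species
topology on ``k`` species is built by uniform random joins and instantiated
twice under the duplication node, so the two clades match species for
species. Every edge length is drawn i.i.d. from a base distribution
(exponential by default — positive and right-skewed, like real
substitutions-per-site branch lengths) and multiplied by the clade's rate
multiplier, so the ratio rB/rA is the controlled ground truth the tests
should detect. An optional species-dropout probability removes species from
clade B, emulating loss of a dispensable duplicate in some lineages, which
makes clade A's species set a strict superset.

``power_sweep`` turns this into a calibration harness: rejection rates per
test across replicates, at rA = rB (type-I error) or rA != rB (power).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .errors import CladeDivError
from .pruning import prune_to_leaves
from .tree import CladeRef, Node, PhyloTree
from .workflow import AnalysisConfig, compare_clades

__all__ = ["SimSpec", "SimTruth", "simulate_duplicated_tree", "power_sweep"]

DEFAULT_SPECIES_PATTERN = "sp[0-9]+"


@dataclass(frozen=True)
class SimSpec:
    """Parameters of one simulated duplicated gene tree.

    ``rate_a``/``rate_b`` scale every edge of the respective clade, so the
    expected within-clade branch length is ``rate * base_mean``.
    ``dropout_b`` is the per-species probability of losing the clade-B copy.
    """

    n_species: int = 20
    rate_a: float = 1.0
    rate_b: float = 1.0
    base: Literal["exponential", "fixed"] = "exponential"
    base_mean: float = 0.1
    dropout_b: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 3:
            raise CladeDivError("need at least 3 species")
        if self.rate_a <= 0 or self.rate_b <= 0:
            raise CladeDivError("rate multipliers must be positive")
        if not (0.0 <= self.dropout_b < 1.0):
            raise CladeDivError("dropout_b must be in [0, 1)")
        if self.base_mean <= 0:
            raise CladeDivError("base_mean must be positive")


@dataclass(frozen=True)
class SimTruth:
    """Ground truth of a simulated tree."""

    true_ratio: float  # rate_b / rate_a
    dropped_species: tuple[str, ...]
    duplication_label: str = "duplication"
    clade_a_label: str = "cladeA"
    clade_b_label: str = "cladeB"
    species: tuple[str, ...] = field(default_factory=tuple)


def _random_topology(k: int, rng: np.random.Generator) -> Node:
    """Random rooted binary shape on k leaves by uniform pairwise joins.

    Leaves carry species tags ``sp1`` .. ``sp<k>`` in their labels (filled
    in later per clade).
    """
    nodes = [Node(label=f"sp{i + 1}") for i in range(k)]
    while len(nodes) > 1:
        i, j = sorted(rng.choice(len(nodes), size=2, replace=False))
        parent = Node()
        parent.add_child(nodes[i])
        parent.add_child(nodes[j])
        nodes = [n for idx, n in enumerate(nodes) if idx not in (i, j)]
        nodes.append(parent)
    return nodes[0]


def _instantiate(
    shape: Node, prefix: str, rate: float, spec: SimSpec, rng: np.random.Generator
) -> Node:
    """Copy the species shape into one clade: relabel leaves and draw edge
    lengths from the base distribution scaled by the clade rate."""

    def draw() -> float:
        if spec.base == "fixed":
            return spec.base_mean * rate
        return float(rng.exponential(spec.base_mean)) * rate

    def build(n: Node) -> Node:
        label = f"{prefix}_{n.label}" if n.is_leaf else None
        out = Node(label=label, length=draw())
        for child in n.children:
            out.add_child(build(child))
        return out

    return build(shape)


def simulate_duplicated_tree(spec: SimSpec) -> tuple[PhyloTree, SimTruth]:
    """One duplicated gene tree plus its ground-truth record.

    Deterministic: the same spec (including seed) yields byte-identical
    Newick output.
    """
    rng = np.random.default_rng(spec.seed)
    shape = _random_topology(spec.n_species, rng)
    species = tuple(f"sp{i + 1}" for i in range(spec.n_species))

    clade_a = _instantiate(shape, "gA", spec.rate_a, spec, rng)
    clade_a.label = "cladeA"
    clade_b = _instantiate(shape, "gB", spec.rate_b, spec, rng)
    clade_b.label = "cladeB"

    dropped: tuple[str, ...] = ()
    if spec.dropout_b > 0:
        mask = rng.random(spec.n_species) < spec.dropout_b
        dropped = tuple(sp for sp, m in zip(species, mask) if m)
        keep = [f"gB_{sp}" for sp, m in zip(species, mask) if not m]
        if len(keep) < 2:
            raise CladeDivError(
                "dropout left fewer than 2 species in clade B; lower "
                "dropout_b or increase n_species"
            )
        if dropped:
            stem = clade_b.length
            tmp_tree = PhyloTree(clade_b.copy_subtree())
            pruned = prune_to_leaves(
                CladeRef(tmp_tree, tmp_tree.root), set(keep)
            )
            clade_b = pruned.tree.root
            clade_b.label = "cladeB"
            clade_b.length = stem

    root = Node(label="duplication")
    root.add_child(clade_a)
    root.add_child(clade_b)
    tree = PhyloTree(root)
    truth = SimTruth(
        true_ratio=spec.rate_b / spec.rate_a,
        dropped_species=dropped,
        species=species,
    )
    return tree, truth


def _replicate_seeds(base_seed: int, replicates: int) -> list[int]:
    ss = np.random.SeedSequence(base_seed)
    return [int(s % (2**31)) for s in ss.generate_state(replicates, np.uint64)]


def power_sweep(
    specs: Sequence[SimSpec],
    replicates: int,
    alpha: float = 0.05,
    species_pattern: str = DEFAULT_SPECIES_PATTERN,
) -> pd.DataFrame:
    """Rejection rate of each test, per spec, over seeded replicates.

    Each replicate simulates a tree, runs the full species-aware comparison
    between the two paralog clades, and records whether each test's p-value
    falls below ``alpha``. With rate_a == rate_b this measures the type-I
    error; otherwise, power.
    """
    if replicates < 50:
        raise CladeDivError("use >= 50 replicates for stable rates")
    if not (0.0 < alpha < 1.0):
        raise CladeDivError("alpha must be in (0, 1)")
    rows = []
    for spec in specs:
        rejections = {"student_t": 0, "welch_t": 0, "mann_whitney_u": 0}
        valid = {k: 0 for k in rejections}
        mean_t = []
        for rep_seed in _replicate_seeds(spec.seed, replicates):
            tree, truth = simulate_duplicated_tree(replace(spec, seed=rep_seed))
            report = compare_clades(
                tree,
                AnalysisConfig(
                    clade_a_label=truth.clade_a_label,
                    clade_b_label=truth.clade_b_label,
                    species_pattern=species_pattern,
                ),
            )
            for t in report.tests:
                if t.error is not None:
                    continue
                valid[t.name] += 1
                if t.p_value < alpha:
                    rejections[t.name] += 1
                if t.name == "student_t":
                    mean_t.append(t.statistic)
        row = {
            "n_species": spec.n_species,
            "rate_a": spec.rate_a,
            "rate_b": spec.rate_b,
            "dropout_b": spec.dropout_b,
            "replicates": replicates,
            "alpha": alpha,
            "mean_student_t": float(np.mean(mean_t)) if mean_t else float("nan"),
        }
        for name in rejections:
            row[f"reject_{name}"] = (
                rejections[name] / valid[name] if valid[name] else float("nan")
            )
        rows.append(row)
    return pd.DataFrame(rows)
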