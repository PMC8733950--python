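"""End-to-end clade-divergence analysis.

Pipeline (fixed order) for two user-designated paralogous clades A and B:

1. map each clade's leaves to species via the regex pattern;
2. within each clade, pick one representative leaf per species (the least
   diverged one);
3. intersect the two species sets;
4. prune each clade to the representatives of the *common* species, with
   branch lengths updated;
5. collect the within-clade branch-length samples (stem edge excluded
   unless requested);
6. run the three two-sample tests;
7. summarise the species sets of the FULL (unpruned) clades — the Venn
   describes clade content, while the tests describe the pruned comparison;
8. assemble a serialisable report.

Without a species pattern steps 1–4 are skipped and every leaf enters the
comparison.
"""

from __future__ import annotations

import hashlib
import logging
import statistics as pystats
from dataclasses import dataclass
from pathlib import Path

from pydantic import BaseModel

from . import __version__
from .errors import CladeSelectionError
from .pruning import BranchLengthSample, PrunedClade, branch_lengths, prune_to_leaves
from .species import (
    SpeciesExtractor,
    SpeciesSetSummary,
    UnmatchedPolicy,
    clade_species_map,
    select_representative,
    species_set_analysis,
)
from .stats import TestResult, run_all_tests
from .tree import CladeRef, PhyloTree, find_mrca, write_newick

logger = logging.getLogger(__name__)

__all__ = [
    "AnalysisConfig",
    "DivergenceReport",
    "CladeSummary",
    "resolve_clades",
    "compare_clades",
    "write_report",
    "load_report",
]


@dataclass(frozen=True)
class AnalysisConfig:
    """How the comparison is to be run.

    Each clade is designated either by a set of leaf names (its MRCA defines
    the clade) or by an internal-node label; exactly one of the two per
    clade.
    """

    clade_a_leaves: frozenset[str] | None = None
    clade_b_leaves: frozenset[str] | None = None
    clade_a_label: str | None = None
    clade_b_label: str | None = None
    species_pattern: str | None = None
    unmatched_policy: UnmatchedPolicy = "exclude"
    include_stem: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        for side in "ab":
            leaves = getattr(self, f"clade_{side}_leaves")
            label = getattr(self, f"clade_{side}_label")
            if (leaves is None) == (label is None):
                raise CladeSelectionError(
                    f"clade {side.upper()}: give either a leaf set or a "
                    "node label (exactly one)"
                )
            if leaves is not None and not leaves:
                raise CladeSelectionError(f"clade {side.upper()}: empty leaf set")


class CladeSummary(BaseModel):
    """Per-clade block of the report."""

    name: str
    designation: str
    leaf_count: int
    species_count: int | None = None
    representatives: dict[str, str] | None = None
    unmatched_leaves: list[str] | None = None
    pruned_leaf_count: int | None = None
    sample_size: int
    mean_length: float
    median_length: float


class SpeciesSetBlock(BaseModel):
    """Venn-style species summary of the full (unpruned) clades."""

    common: int
    unique_a: int
    unique_b: int
    relation: str
    common_species: list[str]
    unique_a_species: list[str]
    unique_b_species: list[str]

    @classmethod
    def from_summary(cls, s: SpeciesSetSummary) -> "SpeciesSetBlock":
        return cls(
            common=s.common,
            unique_a=s.unique_a,
            unique_b=s.unique_b,
            relation=s.relation,
            common_species=list(s.common_species),
            unique_a_species=list(s.unique_a_species),
            unique_b_species=list(s.unique_b_species),
        )


class Provenance(BaseModel):
    tool: str = "cladediv"
    version: str = __version__
    species_pattern: str | None = None
    unmatched_policy: str = "exclude"
    include_stem: bool = False
    input_sha256: str = ""


class DivergenceReport(BaseModel):
    """Complete result of one clade-divergence analysis.

    ``samples`` holds the two branch-length samples verbatim (plot-ready for
    a boxplot); ``species_sets`` holds Venn counts when a pattern was given.
    """

    clade_a: CladeSummary
    clade_b: CladeSummary
    tests: list[TestResult]
    species_sets: SpeciesSetBlock | None = None
    samples: dict[str, list[float]]
    provenance: Provenance


def resolve_clades(tree: PhyloTree, config: AnalysisConfig) -> tuple[CladeRef, CladeRef]:
    """Resolve both clade designators and verify they are disjoint.

    Nested or overlapping clades are rejected; non-sibling (but disjoint)
    clades are allowed with a warning, since the user must know where the
    duplication node is.
    """

    def resolve(leaves: frozenset[str] | None, label: str | None) -> CladeRef:
        if label is not None:
            node = tree.find_node(label)
            if node is None:
                raise CladeSelectionError(f"no node labelled {label!r} in tree")
        else:
            node = find_mrca(tree, set(leaves))
        return CladeRef(tree, node)

    a = resolve(config.clade_a_leaves, config.clade_a_label)
    b = resolve(config.clade_b_leaves, config.clade_b_label)

    def is_ancestor(anc, node) -> bool:
        while node is not None:
            if node is anc:
                return True
            node = node.parent
        return False

    if a.node is b.node or is_ancestor(a.node, b.node) or is_ancestor(b.node, a.node):
        raise CladeSelectionError(
            "clades must be disjoint paralogous sister groups "
            "(one designated clade contains the other)"
        )
    if a.node.parent is not b.node.parent:
        logger.warning(
            "clade roots are not siblings; make sure both descend from the "
            "intended duplication node"
        )
    return a, b


def _summary(
    name: str,
    designation: str,
    clade: CladeRef,
    sample: BranchLengthSample,
    species_count: int | None = None,
    representatives: dict[str, str] | None = None,
    unmatched: list[str] | None = None,
    pruned: PrunedClade | None = None,
) -> CladeSummary:
    return CladeSummary(
        name=name,
        designation=designation,
        leaf_count=len(clade.leaves()),
        species_count=species_count,
        representatives=representatives,
        unmatched_leaves=unmatched,
        pruned_leaf_count=len(pruned.kept) if pruned is not None else None,
        sample_size=len(sample),
        mean_length=float(pystats.fmean(sample.values)),
        median_length=float(pystats.median(sample.values)),
    )


def compare_clades(tree: PhyloTree, config: AnalysisConfig) -> DivergenceReport:
    """Run the full analysis and return the assembled report."""
    clade_a, clade_b = resolve_clades(tree, config)
    desig_a = config.clade_a_label or "MRCA(" + ",".join(sorted(config.clade_a_leaves)) + ")"
    desig_b = config.clade_b_label or "MRCA(" + ",".join(sorted(config.clade_b_leaves)) + ")"

    species_block: SpeciesSetBlock | None = None
    extras_a: dict = {}
    extras_b: dict = {}

    if config.species_pattern is not None:
        extractor = SpeciesExtractor(config.species_pattern, config.unmatched_policy)
        map_a = clade_species_map(clade_a, extractor)
        map_b = clade_species_map(clade_b, extractor)
        reps_a = {
            sp: select_representative(clade_a, leaves)
            for sp, leaves in map_a.by_species.items()
        }
        reps_b = {
            sp: select_representative(clade_b, leaves)
            for sp, leaves in map_b.by_species.items()
        }
        common = sorted(map_a.species & map_b.species)
        if len(common) < 2:
            raise CladeSelectionError(
                "need >= 2 common species for a pruned comparison; "
                f"clade A species = {sorted(map_a.species)}, "
                f"clade B species = {sorted(map_b.species)}"
            )
        for sp in sorted(map_a.species - set(common)):
            logger.info("clade A: species %s not common, leaves excluded", sp)
        for sp in sorted(map_b.species - set(common)):
            logger.info("clade B: species %s not common, leaves excluded", sp)
        pruned_a = prune_to_leaves(clade_a, {reps_a[sp] for sp in common})
        pruned_b = prune_to_leaves(clade_b, {reps_b[sp] for sp in common})
        sample_a = branch_lengths(pruned_a, include_stem=config.include_stem)
        sample_b = branch_lengths(pruned_b, include_stem=config.include_stem)
        species_block = SpeciesSetBlock.from_summary(species_set_analysis(map_a, map_b))
        extras_a = dict(
            species_count=len(map_a), representatives=reps_a,
            unmatched=map_a.unmatched, pruned=pruned_a,
        )
        extras_b = dict(
            species_count=len(map_b), representatives=reps_b,
            unmatched=map_b.unmatched, pruned=pruned_b,
        )
    else:
        sample_a = branch_lengths(clade_a, include_stem=config.include_stem)
        sample_b = branch_lengths(clade_b, include_stem=config.include_stem)

    tests = run_all_tests(sample_a, sample_b)
    digest = hashlib.sha256(write_newick(tree).encode()).hexdigest()
    return DivergenceReport(
        clade_a=_summary("A", desig_a, clade_a, sample_a, **extras_a),
        clade_b=_summary("B", desig_b, clade_b, sample_b, **extras_b),
        tests=tests,
        species_sets=species_block,
        samples={
            "clade_a": [float(v) for v in sample_a.values],
            "clade_b": [float(v) for v in sample_b.values],
        },
        provenance=Provenance(
            species_pattern=config.species_pattern,
            unmatched_policy=config.unmatched_policy,
            include_stem=config.include_stem,
            input_sha256=digest,
        ),
    )


def write_report(
    report: DivergenceReport,
    path: str | Path,
    tsv_path: str | Path | None = None,
) -> None:
    """Serialise the report to JSON (schema shipped with the package) and
    optionally a flat TSV of the test panel."""
    Path(path).write_text(report.model_dump_json(indent=2) + "\n")
    if tsv_path is not None:
        lines = ["test\tstatistic\tdf\tp_value\tn1\tn2\tmethod\terror"]
        for t in report.tests:
            lines.append(
                "\t".join(
                    "" if v is None else str(v)
                    for v in (t.name, t.statistic, t.df, t.p_value, t.n1, t.n2,
                              t.method, t.error)
                )
            )
        Path(tsv_path).write_text("\n".join(lines) + "\n")


def load_report(path: str | Path) -> DivergenceReport:
    return DivergenceReport.model_validate_json(Path(path).read_text())
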