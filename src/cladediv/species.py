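"""Species identification from leaf labels and species-set comparison.

Gene-tree leaves usually embed a species identifier in the sequence name
(e.g. an NCBI taxonomy id such as ``taxid_9606``). A user-supplied regular
expression extracts that identifier; the first match found in the label wins,
so the pattern is a substring pattern, not a full-label match.

Once both clades are mapped species -> leaves, two questions follow:

* which single leaf represents a species that contributed several sequences
  (paralogs or isoforms) to a clade — the least diverged one, measured by
  path length to the clade root, with lexicographically-smallest label as a
  deterministic tie-break;
* how the two clades' species sets relate (equal / overlap / one a superset
  of the other / disjoint). A clade whose species set strictly contains the
  other's is the candidate essential copy: no lineage tolerated losing it.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Literal

from .errors import CladeSelectionError, SpeciesError
from .tree import CladeRef, Node, distance_to_clade_root

logger = logging.getLogger(__name__)

__all__ = [
    "SpeciesExtractor",
    "SpeciesMap",
    "SpeciesSetSummary",
    "extract_species",
    "clade_species_map",
    "select_representative",
    "species_set_analysis",
]

UnmatchedPolicy = Literal["exclude", "error"]


@dataclass(frozen=True)
class SpeciesExtractor:
    """Regex rule mapping a leaf label to a species identifier.

    ``policy`` controls leaves the pattern does not match: ``"exclude"``
    drops them with a logged warning (the default), ``"error"`` aborts.
    """

    pattern: str
    policy: UnmatchedPolicy = "exclude"
    _compiled: re.Pattern = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        try:
            compiled = re.compile(self.pattern)
        except re.error as exc:
            raise SpeciesError(f"invalid species pattern {self.pattern!r}: {exc}")
        object.__setattr__(self, "_compiled", compiled)

    def __call__(self, label: str) -> str | None:
        return extract_species(label, self)


def extract_species(leaf_label: str, extractor: SpeciesExtractor) -> str | None:
    """Species id = substring of the first pattern match; None if no match."""
    m = extractor._compiled.search(leaf_label)
    return m.group(0) if m else None


@dataclass
class SpeciesMap:
    """Species id -> leaf labels within one clade, plus unmatched leaves."""

    by_species: dict[str, list[str]]
    unmatched: list[str]

    @property
    def species(self) -> set[str]:
        return set(self.by_species)

    def __len__(self) -> int:
        return len(self.by_species)


def clade_species_map(clade: CladeRef, extractor: SpeciesExtractor) -> SpeciesMap:
    """Group the clade's leaves by extracted species identifier."""
    by_species: dict[str, list[str]] = {}
    unmatched: list[str] = []
    for leaf in clade.leaves():
        sp = extract_species(leaf.label, extractor)
        if sp is None:
            unmatched.append(leaf.label)
        else:
            by_species.setdefault(sp, []).append(leaf.label)
    if unmatched:
        if extractor.policy == "error":
            raise SpeciesError(
                f"pattern {extractor.pattern!r} matched no species id in "
                f"leaves: {', '.join(unmatched)}"
            )
        logger.warning(
            "excluding %d leaves without a species id match: %s",
            len(unmatched),
            ", ".join(unmatched),
        )
    return SpeciesMap(by_species=by_species, unmatched=unmatched)


def select_representative(clade: CladeRef, leaves: list[str | Node]) -> str:
    """The least diverged of ``leaves``: minimal path length to the clade
    root, ties broken by lexicographically smallest label.

    When a species contributed several sequences to a clade, the more
    diverged copies may reflect relaxed selection or sequencing artefacts;
    keeping the least diverged one is the conservative choice.
    """
    if not leaves:
        raise CladeSelectionError("representative selection needs >= 1 leaf")
    labels = [leaf.label if isinstance(leaf, Node) else leaf for leaf in leaves]
    return min(labels, key=lambda lab: (distance_to_clade_root(clade, lab), lab))


Relation = Literal["A_superset", "B_superset", "equal", "overlap", "disjoint"]


@dataclass(frozen=True)
class SpeciesSetSummary:
    """Venn-style comparison of two clades' species sets."""

    common: int
    unique_a: int
    unique_b: int
    common_species: tuple[str, ...]
    unique_a_species: tuple[str, ...]
    unique_b_species: tuple[str, ...]
    relation: Relation


def species_set_analysis(map_a: SpeciesMap, map_b: SpeciesMap) -> SpeciesSetSummary:
    """Intersection/difference counts and the superset relation.

    A clade is declared a superset only when the other clade has no unique
    species AND the intersection is nonempty — a vacuous superset over an
    empty set carries no signal about essentiality.
    """
    a, b = map_a.species, map_b.species
    if not a and not b:
        raise SpeciesError("both species sets are empty; nothing to compare")
    common = a & b
    only_a = a - b
    only_b = b - a
    if common and not only_a and not only_b:
        relation: Relation = "equal"
    elif common and not only_b:
        relation = "A_superset"
    elif common and not only_a:
        relation = "B_superset"
    elif common:
        relation = "overlap"
    else:
        relation = "disjoint"
    return SpeciesSetSummary(
        common=len(common),
        unique_a=len(only_a),
        unique_b=len(only_b),
        common_species=tuple(sorted(common)),
        unique_a_species=tuple(sorted(only_a)),
        unique_b_species=tuple(sorted(only_b)),
        relation=relation,
    )
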