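"""The pruning operator: restrict families to offspring carrying the known
disease allele/genotype at locus A (or an associated marker allele).

Parents are always retained, irrespective of genotype, because they are
the connecting subjects.  Offspring failing the carrier predicate are
removed entirely from the analysis file.  A family whose remaining
offspring count falls below two is dropped: removing non-carrier
offspring can turn a two-offspring family into an uninformative trio.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .pedigree import MISSING, GeneticMap, Individual, Pedigree
from .trait_models import TwoLocusTraitModel

__all__ = [
    "CarrierPredicate",
    "PredicateError",
    "ReductionStats",
    "offspring_carries",
    "prune_family",
    "prune_dataset",
]

MIN_REMAINING_OFFSPRING = 2


class PredicateError(ValueError):
    """The carrier predicate cannot be resolved for an individual."""


@dataclass(frozen=True)
class CarrierPredicate:
    """Who counts as a carrier at the stratification locus.

    target "truth-at-A" uses the true disease-locus genotype (available
    from the simulator or a truth sidecar); target "marker-allele" uses
    the observed genotype at a marker.  rule "allele-carrier" keeps
    offspring with at least ``min_copies`` of the allele; rule
    "disease-genotype" keeps offspring whose genotype is disease-causing
    under ``mode`` (>= 1 copy if dominant, 2 copies if recessive).
    """

    target: str  # "truth-at-A" | "marker-allele"
    rule: str  # "allele-carrier" | "disease-genotype"
    locus_index: int
    allele: int = 1
    mode: str = "dominant"
    min_copies: int = 1

    def __post_init__(self):
        if self.target not in ("truth-at-A", "marker-allele"):
            raise ValueError(f"unknown predicate target {self.target!r}")
        if self.rule not in ("allele-carrier", "disease-genotype"):
            raise ValueError(f"unknown predicate rule {self.rule!r}")
        if self.target == "marker-allele" and self.rule == "disease-genotype":
            raise ValueError(
                "marker-allele pruning uses observed marker genotypes only; "
                "use the allele-carrier rule"
            )

    @classmethod
    def truth_at_A(cls, trait: TwoLocusTraitModel, gmap: GeneticMap):
        """Default rule for a known disease allele at A: carriers when the
        mode at A is dominant, the full disease genotype when recessive."""
        return cls(
            target="truth-at-A",
            rule="disease-genotype",
            locus_index=gmap.index_A,
            allele=1,
            mode=trait.mode_A,
        )

    @classmethod
    def marker_allele(cls, gmap: GeneticMap, allele: int = 1, min_copies: int = 1):
        """Prune on the associated marker allele (>= min_copies copies)."""
        return cls(
            target="marker-allele",
            rule="allele-carrier",
            locus_index=gmap.index_ld_marker,
            allele=allele,
            min_copies=min_copies,
        )


def offspring_carries(ind: Individual, pred: CarrierPredicate) -> bool:
    """Evaluate the carrier predicate for one individual."""
    g = ind.genotypes[pred.locus_index]
    if MISSING in (int(g[0]), int(g[1])):
        raise PredicateError(
            f"individual {ind.id}: genotype at locus {pred.locus_index + 1} "
            "is missing; predicate unresolvable"
        )
    copies = int(g[0] == pred.allele) + int(g[1] == pred.allele)
    if pred.rule == "allele-carrier":
        return copies >= pred.min_copies
    return copies >= 1 if pred.mode == "dominant" else copies == 2


def prune_family(ped: Pedigree, pred: CarrierPredicate) -> Pedigree | None:
    """Parents kept; non-carrier offspring removed; None if uninformative.

    A family is dropped (returns None) when fewer than two offspring
    remain, i.e. fewer than four members.
    """
    kept = list(ped.founders)
    kept += [o for o in ped.offspring if offspring_carries(o, pred)]
    if len(kept) - len(ped.founders) < MIN_REMAINING_OFFSPRING:
        return None
    return Pedigree(family_id=ped.family_id, members=kept)


@dataclass
class ReductionStats:
    """Family and subject counts before/after pruning."""

    families_before: int
    families_after: int
    subjects_before: int
    subjects_after: int

    @property
    def family_reduction_pct(self) -> float:
        return 100.0 * (1.0 - self.families_after / self.families_before)

    @property
    def subject_reduction_pct(self) -> float:
        return 100.0 * (1.0 - self.subjects_after / self.subjects_before)

    @property
    def families_remaining_pct(self) -> float:
        return 100.0 * self.families_after / self.families_before

    @property
    def subjects_remaining_pct(self) -> float:
        return 100.0 * self.subjects_after / self.subjects_before


def prune_dataset(
    dataset: list[Pedigree], pred: CarrierPredicate
) -> tuple[list[Pedigree], ReductionStats]:
    """Prune every family; returns the informative families plus tallies.

    Bookkeeping convention: the family count after pruning includes only
    informative families (>= 2 remaining offspring) -- the ones returned
    for analysis -- while the subject count after pruning includes the
    parents and carrier offspring of *every* family, because families
    pruned down to trios stay in the sample; they are merely uninformative
    for linkage.  Subject loss is therefore exactly the removed non-carrier
    offspring.
    """
    pruned = []
    subjects_after = 0
    for ped in dataset:
        carriers = sum(1 for o in ped.offspring if offspring_carries(o, pred))
        subjects_after += 2 + carriers
        p = prune_family(ped, pred)
        if p is not None:
            pruned.append(p)
    stats = ReductionStats(
        families_before=len(dataset),
        families_after=len(pruned),
        subjects_before=sum(p.n_members for p in dataset),
        subjects_after=subjects_after,
    )
    return pruned, stats
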