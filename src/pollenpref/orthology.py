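"""Reciprocal ortholog expression-conservancy between two species' late pollen-preferred sets.

A query gene is *conserved* when at least one of its orthologs in the other
species is itself late pollen-preferred there (the any-ortholog rule;
many-to-many maps are allowed). The conservancy percentage uses the full
query late set as denominator.
"""

from __future__ import annotations

from dataclasses import dataclass

from .conservation import GeneSet
from .enrichment import round_half_up
from .io import OrthologMap, ValidationError


@dataclass
class ConservancyResult:
    n_query: int
    n_with_ortholog: int
    n_conserved: int
    percent_conserved: float  # 100 * n_conserved / n_query, 2 dp


def conservancy(set_a: GeneSet, set_b: GeneSet, omap: OrthologMap,
                direction: str = "a_to_b") -> ConservancyResult:
    """Expression conservancy of ``set_a``'s genes in species B (or reverse).

    ``direction="a_to_b"`` treats set_a as the query (its loci on the map's
    A side) and set_b as the other species' late set; ``"b_to_a"`` swaps
    the roles.
    """
    if not omap.pairs:
        raise ValidationError("ortholog map is empty")
    if direction == "a_to_b":
        query, other = set_a, set_b
        partners = omap.partners_of_a()
    elif direction == "b_to_a":
        query, other = set_b, set_a
        partners = omap.partners_of_b()
    else:
        raise ValueError(f"direction must be a_to_b or b_to_a, got {direction!r}")
    if len(query) == 0:
        raise ValidationError("query gene set is empty")

    n_with_ortholog = 0
    n_conserved = 0
    for gene in query.locus_ids:
        p = partners.get(gene)
        if p:
            n_with_ortholog += 1
            if p & other.locus_ids:
                n_conserved += 1
    percent = round_half_up(100.0 * n_conserved / len(query), 2)
    return ConservancyResult(len(query), n_with_ortholog, n_conserved, percent)


def divergent_partition(set_a: GeneSet, set_b: GeneSet, omap: OrthologMap,
                        direction: str = "a_to_b",
                        ) -> tuple[set[str], set[str]]:
    """Split the query late set into (conserved, divergent) gene sets.

    Conserved genes are those counted by :func:`conservancy`; divergent is
    the remainder (genes with no ortholog plus genes whose orthologs are not
    late-preferred). The partition is exhaustive and disjoint.
    """
    query = set_a if direction == "a_to_b" else set_b
    other = set_b if direction == "a_to_b" else set_a
    partners = (omap.partners_of_a() if direction == "a_to_b"
                else omap.partners_of_b())
    conserved = {g for g in query.locus_ids
                 if partners.get(g) and partners[g] & other.locus_ids}
    divergent = query.locus_ids - conserved
    return conserved, divergent
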