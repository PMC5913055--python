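"""GO fold-enrichment over a term-assignment universe, with hypergeometric testing.

The universe is term *assignments* (gene-term pairs), not genes: the genome
total is the number of GO assignments genome-wide and the query total is the
number of assignments carried by the query genes. For a term with ``a``
genome-wide assignments and ``b`` assignments among the query genes,

    expected  c = a * total_query / total_genome
    fold      d = b / c
    p         = P[X >= b],  X ~ Hypergeom(total_genome, a, total_query)

Terms are called enriched when p <= 0.05 and fold >= 2 (no multiple-testing
correction by default; Benjamini-Hochberg is available as an option).
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import pandas as pd
from scipy import stats

from .io import GOAnnotation, ValidationError


@dataclass
class EnrichmentRow:
    """One GO term's enrichment statistics (one report-table row)."""

    term_id: str
    genome_repeats: int   # a: genome-wide assignments of the term
    observed: int         # b: assignments among query genes
    expected: float       # c = a * total_query / total_genome
    fold: float           # d = b / c
    p_value: float

    def rounded(self, dp_expected: int = 1, dp_fold: int = 1) -> tuple[float, float]:
        """(expected, fold) rounded half-up for report display."""
        return (round_half_up(self.expected, dp_expected),
                round_half_up(self.fold, dp_fold))


def round_half_up(x: float, dp: int) -> float:
    q = Decimal(10) ** -dp
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


def hypergeom_p(genome_repeats: int, observed: int,
                total_genome: int, total_query: int) -> float:
    """Upper-tail hypergeometric probability of >= ``observed`` successes.

    Population ``total_genome`` assignments of which ``genome_repeats`` carry
    the term; ``total_query`` assignments are drawn without replacement.
    """
    if not (0 <= genome_repeats <= total_genome):
        raise ValidationError("genome_repeats out of [0, total_genome]")
    if not (0 <= total_query <= total_genome):
        raise ValidationError("total_query out of [0, total_genome]")
    if observed > min(genome_repeats, total_query) or observed < 0:
        raise ValidationError(
            f"observed={observed} impossible with successes={genome_repeats}, "
            f"draws={total_query}")
    return float(stats.hypergeom.sf(observed - 1, total_genome,
                                    genome_repeats, total_query))


def fold_enrichment(query_genes: set[str],
                    annotation: GOAnnotation) -> list[EnrichmentRow]:
    """Per-term fold enrichment and hypergeometric p for the query gene set.

    One row per term with at least one query assignment. Values are kept at
    full precision; rounding happens only at report time.
    """
    if not query_genes:
        raise ValidationError("query gene set is empty")
    if not annotation.term_to_genes:
        raise ValidationError("annotation has no terms")
    total_genome = annotation.total_genome_repeats

    observed_per_term = {}
    for term, genes in annotation.term_to_genes.items():
        b = len(genes & query_genes)
        if b > 0:
            observed_per_term[term] = b
    total_query = sum(observed_per_term.values())

    rows = []
    for term, b in sorted(observed_per_term.items()):
        a = annotation.genome_term_repeats[term]
        if b > a:
            raise ValidationError(
                f"term {term!r}: observed {b} exceeds genome repeats {a}")
        c = a * total_query / total_genome
        rows.append(EnrichmentRow(
            term_id=term, genome_repeats=a, observed=b, expected=c,
            fold=b / c,
            p_value=hypergeom_p(a, b, total_genome, total_query),
        ))
    return rows


def filter_enriched(rows: list[EnrichmentRow], p_max: float = 0.05,
                    fold_min: float = 2.0,
                    fdr: bool = False) -> list[EnrichmentRow]:
    """Rows with p <= p_max and fold >= fold_min, sorted by fold descending.

    With ``fdr=True`` the p gate is applied to Benjamini-Hochberg adjusted
    p-values across all input rows instead of the raw p-values.
    """
    if fdr and rows:
        adjusted = benjamini_hochberg([r.p_value for r in rows])
        kept = [r for r, q in zip(rows, adjusted)
                if q <= p_max and r.fold >= fold_min]
    else:
        kept = [r for r in rows if r.p_value <= p_max and r.fold >= fold_min]
    return sorted(kept, key=lambda r: (-r.fold, r.term_id))


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """BH-adjusted p-values, in input order."""
    m = len(p_values)
    order = sorted(range(m), key=lambda i: p_values[i])
    adjusted = [0.0] * m
    running = 1.0
    for rank_from_end, i in enumerate(reversed(order)):
        rank = m - rank_from_end
        running = min(running, p_values[i] * m / rank)
        adjusted[i] = running
    return adjusted


def bin_tally(query_genes: set[str], bin_map: dict[str, str]) -> dict[str, int]:
    """Count query genes per functional bin; unmapped genes go to "unassigned"."""
    tally: dict[str, int] = {}
    for gene in query_genes:
        bin_label = bin_map.get(gene, "unassigned")
        tally[bin_label] = tally.get(bin_label, 0) + 1
    return tally


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Report-shaped table (term, a, b, c, d, p) with c and d at 1 dp."""
    records = []
    for r in rows:
        c, d = r.rounded()
        records.append((r.term_id, r.genome_repeats, r.observed, c, d, r.p_value))
    return pd.DataFrame(records, columns=["term_id", "genome_repeats",
                                          "observed", "expected", "fold",
                                          "p_value"])
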