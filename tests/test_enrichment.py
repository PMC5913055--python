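"""GO fold-enrichment arithmetic, hypergeometric testing, and functional-bin tallies."""

from fractions import Fraction
from math import comb

import pytest

from pollenpref import (GOAnnotation, ValidationError, bin_tally,
                        filter_enriched, fold_enrichment, hypergeom_p)
from pollenpref.enrichment import (EnrichmentRow, benjamini_hochberg,
                                   round_half_up)

# genome-wide term-assignment totals of the reference rice GO Slim table
TOTAL_GENOME = 39_571
TOTAL_QUERY = 547


def exact_upper_tail(population: int, successes: int, draws: int,
                     observed: int) -> Fraction:
    """Brute-force hypergeometric upper tail by enumeration (oracle)."""
    total = Fraction(0)
    for k in range(observed, min(successes, draws) + 1):
        total += Fraction(comb(successes, k) * comb(population - successes,
                                                    draws - k),
                          comb(population, draws))
    return total


def _annotation_with_totals(observed_terms: dict[str, tuple[int, int]],
                            total_genome: int, total_query_target: int):
    """Annotation + query genes realizing given (a, b) per term with the
    stated totals; filler terms absorb the remaining assignments."""
    term_to_genes: dict[str, set] = {}
    repeats: dict[str, int] = {}
    query: set = set()
    gene_counter = 0
    used_query = 0
    for term, (a, b) in observed_terms.items():
        genes = set()
        for _ in range(b):
            g = f"q{gene_counter}"
            gene_counter += 1
            genes.add(g)
            query.add(g)
        term_to_genes[term] = genes
        repeats[term] = a
        used_query += b
    # one filler term carries the remaining query assignments: a query gene
    # annotated k times contributes k assignments via k filler terms
    remaining = total_query_target - used_query
    for i in range(remaining):
        t = f"filler{i}"
        g = f"qf{i}"
        query.add(g)
        term_to_genes[t] = {g}
        repeats[t] = 1
    used_genome = sum(repeats.values())
    repeats["background"] = total_genome - used_genome
    term_to_genes["background"] = set()
    ann = GOAnnotation(term_to_genes=term_to_genes,
                       genome_term_repeats=repeats,
                       total_genome_repeats=total_genome)
    return ann, query


# Reference GO Slim rows: (genome repeats a, query repeats b) -> printed fold
REFERENCE_ROWS = {
    "phosphatidylcholine metabolic process": (13, 4, 22.3),
    "cell wall modification": (46, 11, 17.3),
    "gibberellin metabolic process": (20, 5, 18.1),
    "potassium ion transport": (203, 9, 3.2),
    "ATP biosynthetic process": (99, 4, 2.9),
}


class TestFoldEnrichment:
    def test_reference_table_folds_reproduce(self):
        """Fold enrichment over the term-assignment universe reproduces the
        published per-term fold values at 1 dp."""
        ann, query = _annotation_with_totals(
            {t: (a, b) for t, (a, b, _) in REFERENCE_ROWS.items()},
            TOTAL_GENOME, TOTAL_QUERY)
        rows = {r.term_id: r for r in fold_enrichment(query, ann)}
        total_query = sum(r.observed for r in rows.values())
        assert total_query == TOTAL_QUERY
        for term, (a, b, printed_fold) in REFERENCE_ROWS.items():
            r = rows[term]
            assert (r.genome_repeats, r.observed) == (a, b)
            _, fold_1dp = r.rounded()
            assert fold_1dp == pytest.approx(printed_fold, abs=0.1)

    def test_whole_genome_query_has_unit_fold(self):
        genes = [f"g{i}" for i in range(10)]
        pairs = [(g, f"t{i % 3}") for i, g in enumerate(genes)]
        ann = GOAnnotation.from_pairs(pairs)
        rows = fold_enrichment(set(genes), ann)
        for r in rows:
            assert r.fold == pytest.approx(1.0)

    def test_sum_of_observed_equals_total_query_assignments(self):
        ann, query = _annotation_with_totals(
            {"t1": (10, 3), "t2": (5, 2)}, 1000, 20)
        rows = fold_enrichment(query, ann)
        assert sum(r.observed for r in rows) == 20

    def test_fold_is_observed_over_expected(self):
        ann, query = _annotation_with_totals({"t1": (10, 3)}, 1000, 10)
        (row,) = [r for r in fold_enrichment(query, ann) if r.term_id == "t1"]
        assert row.expected == pytest.approx(10 * 10 / 1000)
        assert row.fold == pytest.approx(row.observed / row.expected, rel=1e-9)

    def test_observed_exceeding_genome_repeats_is_fatal(self):
        ann = GOAnnotation(term_to_genes={"t": {"g1", "g2"}},
                           genome_term_repeats={"t": 2},
                           total_genome_repeats=2)
        ann.genome_term_repeats["t"] = 1  # corrupt after validation
        ann.total_genome_repeats = 1
        with pytest.raises(ValidationError):
            fold_enrichment({"g1", "g2"}, ann)

    def test_empty_query_is_fatal(self):
        ann = GOAnnotation.from_pairs([("g", "t")])
        with pytest.raises(ValidationError):
            fold_enrichment(set(), ann)


class TestHypergeomP:
    def test_enumeration_example(self):
        # population 10, successes 4, draws 5, observed >= 3 -> 66/252
        assert hypergeom_p(4, 3, 10, 5) == pytest.approx(66 / 252)

    def test_zero_observed_is_certain(self):
        assert hypergeom_p(4, 0, 10, 5) == pytest.approx(1.0)

    def test_saturated_draw_is_certain(self):
        assert hypergeom_p(10, 10, 10, 10) == pytest.approx(1.0)

    def test_matches_enumeration_for_all_small_populations(self):
        """Exact agreement with brute-force enumeration for population <= 12."""
        for population in range(1, 13):
            for successes in range(population + 1):
                for draws in range(population + 1):
                    for observed in range(min(successes, draws) + 1):
                        expected = exact_upper_tail(population, successes,
                                                    draws, observed)
                        got = hypergeom_p(successes, observed, population,
                                          draws)
                        assert got == pytest.approx(float(expected),
                                                    rel=1e-9, abs=1e-12)

    def test_impossible_counts_are_fatal(self):
        with pytest.raises(ValidationError):
            hypergeom_p(4, 5, 10, 5)
        with pytest.raises(ValidationError):
            hypergeom_p(11, 1, 10, 5)


class TestFilterEnriched:
    def _row(self, term, fold, p):
        return EnrichmentRow(term, 10, 5, 5 / fold, fold, p)

    def test_both_gates_and_sort_order(self):
        rows = [self._row("keep_lo", 2.5, 0.01),
                self._row("keep_hi", 22.3, 0.001),
                self._row("fold_fail", 1.5, 0.001),
                self._row("p_fail", 3.0, 0.2)]
        kept = filter_enriched(rows)
        assert [r.term_id for r in kept] == ["keep_hi", "keep_lo"]

    def test_bh_option_is_more_conservative(self):
        # one nominal hit among nine nulls: q = 0.04 * 10 / 1 = 0.4 > 0.05
        mixed = [self._row("a", 5.0, 0.04)] + \
                [self._row(f"t{i}", 5.0, 0.9) for i in range(9)]
        assert len(filter_enriched(mixed, fdr=False)) == 1
        assert len(filter_enriched(mixed, fdr=True)) == 0
        # a very strong hit survives adjustment: q = 0.002 * 10 = 0.02
        strong = [self._row("a", 5.0, 0.002)] + \
                 [self._row(f"t{i}", 5.0, 0.9) for i in range(9)]
        assert len(filter_enriched(strong, fdr=True)) == 1


def test_benjamini_hochberg_known_values():
    # classic worked example: adjusted = min over j>=i of p_(j)*m/j
    ps = [0.01, 0.02, 0.03, 0.04]
    adj = benjamini_hochberg(ps)
    assert adj == pytest.approx([0.04, 0.04, 0.04, 0.04])


class TestBinTally:
    def test_join_and_count(self):
        tally = bin_tally({"g1", "g2", "g3"},
                          {"g1": "CW", "g2": "CW", "g3": "lipid"})
        assert tally == {"CW": 2, "lipid": 1}

    def test_empty_query(self):
        assert bin_tally(set(), {"g": "CW"}) == {}

    def test_unassigned_genes_counted(self):
        tally = bin_tally({"g1", "g2"}, {"g1": "CW"})
        assert tally == {"CW": 1, "unassigned": 1}

    def test_reference_scale_fixture(self):
        """Bins sized like the metabolism overview (48/10/9) tally exactly."""
        bin_map = {}
        genes = set()
        for label, n in [("cell_wall", 48), ("lipid", 10), ("carbohydrate", 9)]:
            for i in range(n):
                g = f"{label}_{i}"
                genes.add(g)
                bin_map[g] = label
        assert bin_tally(genes, bin_map) == {"cell_wall": 48, "lipid": 10,
                                             "carbohydrate": 9}


def test_round_half_up():
    assert round_half_up(9.65, 1) == 9.7
    assert round_half_up(2.25, 1) == 2.3
    assert round_half_up(2.24, 1) == 2.2
    assert round_half_up(9.0909, 2) == 9.09
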