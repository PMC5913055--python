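"""GO fold-enrichment arithmetic over a term-assignment universe.

Reproduces the fold-enrichment values of a published rice GO Slim analysis
from its printed counts: a term with a genome-wide assignments and b
assignments among the query genes, in a genome of 39,571 assignments of
which the query carries 547, has expected count c = a * 547 / 39,571 and
fold d = b / c, with an upper-tail hypergeometric p.
"""

from pollenpref import GOAnnotation, filter_enriched, fold_enrichment

TOTAL_GENOME, TOTAL_QUERY = 39_571, 547
ROWS = {  # term -> (a: genome repeats, b: query repeats)
    "phosphatidylcholine metabolic process": (13, 4),
    "cell wall modification": (46, 11),
    "gibberellin metabolic process": (20, 5),
    "potassium ion transport": (203, 9),
    "ATP biosynthetic process": (99, 4),
}

term_to_genes, repeats, query, i = {}, {}, set(), 0
for term, (a, b) in ROWS.items():
    genes = {f"q{i + k}" for k in range(b)}
    i += b
    query |= genes
    term_to_genes[term], repeats[term] = genes, a
for j in range(TOTAL_QUERY - sum(b for _, b in ROWS.values())):
    g = f"f{j}"
    query.add(g)
    term_to_genes[f"filler{j}"], repeats[f"filler{j}"] = {g}, 1
repeats["rest"] = TOTAL_GENOME - sum(repeats.values())
term_to_genes["rest"] = set()
ann = GOAnnotation(term_to_genes, repeats, TOTAL_GENOME)

rows = [r for r in fold_enrichment(query, ann) if r.term_id in ROWS]
enriched = {r.term_id for r in filter_enriched(rows)}
print(f"{'term':44s} {'a':>4s} {'b':>3s} {'c':>5s} {'fold':>5s}  p")
for r in sorted(rows, key=lambda r: -r.fold):
    c, d = r.rounded()
    flag = "*" if r.term_id in enriched else " "
    print(f"{r.term_id:44s} {r.genome_repeats:4d} {r.observed:3d} "
          f"{c:5.1f} {d:5.1f}{flag} {r.p_value:.2e}")
# '*' marks terms passing p <= 0.05 and fold >= 2; c and d reproduce the
# printed expected-count and fold-enrichment columns at 1 decimal place.
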