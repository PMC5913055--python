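# Methods

## The procedure and its assumptions

The pipeline identifies genes preferentially expressed in the late stages
of pollen development (bi-cellular gametophyte onward: BG, TG, MP, GP) and
conserved across cultivars. It assumes:

- expression values are on the log2 scale and comparable across samples
  after normalization (the package provides quantile normalization as its
  cross-sample normalization; array-level preprocessing such as background
  correction or probe summarization is out of scope and assumed done);
- a probe measures at most one locus, while a locus may be covered by
  several probes;
- "late pollen-preferred" is a property of a cluster centroid, not of a
  single probe: probes are grouped by profile similarity (Euclidean
  k-means) and whole clusters are flagged, which borrows strength across
  probes with the same shape and is robust to per-probe noise;
- conservation across cultivars is a gene-level property: a locus counts
  as conserved when it is late-preferred in every cultivar, regardless of
  which probes carried the signal in each.

## Stage by stage

**Preprocessing.** `log2_transform` clamps linear intensities at a floor
(default 1.0, so the log2 floor is 0) before taking logs; this prevents
−∞ without touching mid-range signal. `quantile_normalize` maps every
column rank-for-rank onto the row-wise mean of per-column sorted values;
tied values receive the mean of the reference values at their tied ranks,
so within-column ranks are preserved exactly. A single-sample matrix is
returned unchanged (with a log notice) since there is nothing to align.
`average_replicates` collapses samples sharing (cultivar, tissue_group,
stage_label) by the arithmetic mean and orders the resulting group columns
by (cultivar, tissue_group, stage_order) — the developmental series, not
alphabetical labels. Replicates are averaged after normalization
(average-last): normalization sees every array, and averaging then
suppresses residual replicate noise.

**Clustering and selection.** `kmeans` uses scikit-learn's KMeans
(Euclidean objective, k-means++ seeding — the standard randomized
farthest-point-style initialization — `n_init` restarts from one seeded
stream, empty clusters re-seeded internally so K stays fixed). Defaults:
K = 36, 10 restarts, 300 iterations, tol 1e-6; the restart with the lowest
within-cluster sum of squares is kept, the objective is recomputable from
assignment + centroids, and a fixed seed gives a bit-identical result.
K = n probes is short-circuited to the trivial zero-objective partition.
The preference index of a cluster is the mean centroid value over
late-pollen sample groups minus the maximum, over every other tissue
group, of that tissue's mean centroid value — a log2 margin against the
*best-expressing* competing tissue, which is deliberately stricter than a
margin against the average tissue. τ defaults to 1.0 log2 (2-fold), the
conventional preferential-expression margin; it is a parameter, not a
constant, because "preferential" has no unique quantitative definition.

**Conservation.** Probe sets collapse to loci under the any-probe rule
(≥ 1 late-preferred probe suffices); `require_all_probes=True` gives the
strict alternative. Probes without a mapping are counted and logged, never
fatal. Intersection is plain set intersection over loci with merged
provenance; it is commutative, associative, and bounded by each input.

**Enrichment.** The universe is term assignments (gene–term pairs), not
genes: the genome total is the count of all GO assignments genome-wide and
the query total is the count of assignments carried by the query genes.
This convention is what makes the expected-count and fold columns of the
reference GO Slim table reproduce arithmetically from its printed per-term
counts and totals (39,571 genome / 547 query assignments). One printed row
("starch biosynthetic process", a = 15, b = 2) shows fold 9.7 where direct
computation gives 2 / (15·547/39,571) ≈ 9.645, which rounds to 9.6 at one
decimal — most plausibly an intermediate-rounding artifact in the original
report. The implementation computes exactly and documents rather than
reproduces the discrepancy. The p-value is the upper-tail hypergeometric probability via
`scipy.stats.hypergeom.sf`; a brute-force rational enumeration over all
draws serves as the test oracle for populations ≤ 12. No multiple-testing
correction is applied by default — the enrichment rule is the raw
p ≤ 0.05 plus fold ≥ 2 gate — with Benjamini–Hochberg available behind
`fdr=True` for users who want it. Report rounding is round-half-up to
1 decimal (Decimal arithmetic, not banker's rounding).

**Orthology.** Many-to-many maps are allowed; one late-preferred partner
suffices (any-ortholog rule), and the conservancy denominator is the full
query late set, not the ortholog-bearing subset — this is the convention
under which the published reciprocal percentages (22.64% of 773, 21.21% of
627) are arithmetic identities of their printed counts. The
conserved/divergent partition is exhaustive and disjoint; divergent genes
split further into those lacking any ortholog and those whose orthologs
are not late-preferred.

**Genetics.** TE = 100 · het/WT is the only formula consistent with both
printed reciprocal-cross values (28/33 → 84.8, 0/35 → 0.0); WT = 0 raises
a distinct undefined-TE error rather than returning a number, because
total wild-type transmission failure is a different biological statement
from TE = 0. The chi-square test excludes zero-weight classes (the 1:1:0
null makes homozygotes structurally impossible, and any observed
homozygote under that null is a hard error, not a bad fit), uses
df = (#positive classes − 1), and applies no continuity correction by
default (Yates available as a flag). The distortion screen flags a cross
when the test rejects at α = 0.05 *and* TE < 50 — under-transmission, not
over-transmission. Proportions use exact Clopper–Pearson intervals from
the beta quantile function.

## The synthetic generator: what it emulates, and what it does not

`gen_expression` emulates the *layout and first-order statistics* of a
two-cultivar staged anther/pollen meta-expression study: one cultivar with
8 anther + 5 pollen stage groups and one with 5 + 3 (mirroring the
published japonica/indica panel shapes), plus root/leaf/seed anatomical
controls, 2 replicates per group; iid Gaussian log2 background with
baseline mean 7.0 and sd 0.5 (typical mid-range array log2 values);
planted genes gaining +4 log2 on all late-pollen samples of their cultivar
(the magnitude of a strong pollen-preferred gene, whose expression sits
above 13 log2 against mid-range background); probes per gene drawn as
1 + Poisson so the expected probe:gene ratio is ≈ 750:627; and a planted
cross-cultivar overlap of 0.8 among 60 planted genes out of 2000.

It does **not** emulate: correlated noise or batch structure between
series, mean–variance dependence, probe-level effects within a gene,
partially graded expression across stages (planted effects switch on at
BG, they do not ramp), or any biological covariance among background
genes. Passing the recovery benchmark therefore shows that the
cluster-preference rule separates a clean, additive late-pollen signal
from Gaussian noise at the stated effect size — it does not certify
performance on real arrays, where normalization artifacts and correlated
tissue programs make the contrast harder.

`gen_go_annotation` plants one designated term at a chosen rate among the
planted genes versus a background rate elsewhere, with Poisson background
terms per gene; genome totals are computed from the generated table.
`gen_ortholog_map` pairs each late-A gene with a late-B partner with
probability equal to the target conserved fraction (else, sometimes, with
a non-late partner), so expected conservancy equals that fraction exactly.
`gen_cross_progeny` draws heterozygote counts binomially with
P(het) = t/(1+t) for true TE t — the sampling model under which the TE
estimator is het/WT. All generators are pure functions of their parameters
and seed.

## Parameters that matter

| parameter | default | units / meaning |
|---|---|---|
| `floor` (log2 transform) | 1.0 | linear intensity clamp; log2 floor 0 |
| `K` | 36 | cluster count |
| `n_restarts` | 10 | k-means restarts, best objective kept |
| `tau` | 1.0 | log2 margin for "late-preferred" (2-fold) |
| `p_max`, `fold_min` | 0.05, 2.0 | enrichment gates |
| `effect_size_log2` | 4.0 | planted late-pollen boost |
| `baseline_mean`, `noise_sd` | 7.0, 0.5 | background log2 distribution |
| `n_genes`, `n_planted` | 2000, 60 | benchmark scale |
| `overlap_fraction` | 0.8 | planted genes shared between cultivars |
| `conserved_fraction` | 0.2 | expected ortholog conservancy |
| `true_te_percent`, `n_progeny` | 85.0, 60 | simulated cross conditions |

The benchmark problem sizes (2000 genes × ~2400 probes, two cultivars,
K = 36; 1000 simulated crosses for the coverage study) are the package's
reference conditions: large enough that cluster structure and coverage are
meaningful, small enough that the full pipeline runs in seconds.

## Numerical choices and degenerate inputs

- Objectives and p-values are kept at full double precision; rounding
  (half-up via `decimal`) happens only at report time.
- Quantile normalization of a single-column matrix is the identity;
  clustering refuses matrices with missing values; K outside [1, n]
  is a hard error.
- Zero flagged clusters is a warning plus an empty set (the pipeline
  completes with empty downstream outputs), not an error: a too-strict τ
  is a legitimate analysis outcome.
- The pipeline derives per-stage sub-seeds from the master seed with a
  seeded generator, so one integer reproduces every stage; reports are
  byte-identical across reruns of the same configuration.
- Config validation rejects unknown sections/keys before any stage runs;
  precedence is CLI flag > config file > built-in default.

## Known limitations

- Cross-platform probe matching, GO DAG propagation, and computation of
  orthology itself (alignment/tree reconciliation) are out of scope; the
  corresponding tables are inputs.
- The enrichment test treats term assignments as exchangeable draws, which
  ignores within-gene correlation of related terms — the cost of matching
  the assignment-universe convention the reference arithmetic requires.
- Merging of overlapping expression series into one matrix per cultivar is
  left to the caller; the loaders accept a single merged matrix.
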