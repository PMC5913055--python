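"""Seeded generators for every input the pipeline consumes.

The generators emulate the structure of a two-cultivar anther/pollen
meta-expression study: staged anatomical panels on the log2 scale with
Gaussian noise, a planted set of late pollen-preferred genes sharing a
specified cross-cultivar overlap, GO annotations with one planted enriched
term, a cross-species ortholog map with a tunable conserved fraction, and
multinomial progeny counts from a heterozygote x wild-type cross with a
known true transmission efficiency.

All generators are pure functions of their parameters and seed; the same
seed yields bit-identical output.

Defaults mirror the study layout: one cultivar with 8 anther and 5 pollen
stage groups, the other with 5 and 3, plus root/leaf/seed anatomical
controls per cultivar; background log2 intensity ~ Normal(7.0, 0.5) with
planted genes gaining +4 log2 on late-pollen samples (the magnitude of a
strong pollen-preferred gene against mid-range background); an expected
probe:gene ratio of ~750:627.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import (CrossCounts, ExpressionMatrix, GOAnnotation, OrthologMap,
                 ProbeGeneMap, SampleMetadata, ValidationError)


@dataclass(frozen=True)
class PanelGroup:
    """One sample group of a cultivar panel."""

    tissue_group: str
    stage_label: str
    stage_order: int
    is_late_pollen: bool
    n_replicates: int = 2


def default_panels() -> dict[str, list[PanelGroup]]:
    """Two-cultivar study layout: staged anther + pollen panels, plus
    anatomical controls."""
    japonica = (
        [PanelGroup("anther", s, i, False)
         for i, s in enumerate(["PMe", "Me", "Me1", "Me2", "Me3", "ACF", "UG", "Fl"])]
        + [PanelGroup("pollen", "UG", 8, False),
           PanelGroup("pollen", "BG", 9, True),
           PanelGroup("pollen", "TG", 10, True),
           PanelGroup("pollen", "MP", 11, True),
           PanelGroup("pollen", "GP", 12, True)]
        + [PanelGroup("root", "other", 13, False),
           PanelGroup("leaf", "other", 14, False),
           PanelGroup("seed", "other", 15, False)]
    )
    indica = (
        [PanelGroup("anther", s, i, False)
         for i, s in enumerate(["PMe", "Me", "ACF", "UG", "Fl"])]
        + [PanelGroup("pollen", "BG", 5, True),
           PanelGroup("pollen", "MP", 6, True),
           PanelGroup("pollen", "GP", 7, True)]
        + [PanelGroup("root", "other", 8, False),
           PanelGroup("leaf", "other", 9, False),
           PanelGroup("seed", "other", 10, False)]
    )
    return {"japonica": japonica, "indica": indica}


@dataclass
class SyntheticExpression:
    """Output bundle of :func:`gen_expression`."""

    matrices: dict[str, ExpressionMatrix]
    metadata: dict[str, SampleMetadata]
    probe_gene_map: ProbeGeneMap
    planted: dict[str, set[str]]      # cultivar -> planted locus ids
    planted_shared: set[str]          # planted in every cultivar
    genes: list[str]


def gen_expression(n_genes: int = 2000,
                   probes_per_gene_mean: float = 750 / 627,
                   panels: dict[str, list[PanelGroup]] | None = None,
                   n_planted: int = 60,
                   effect_size_log2: float = 4.0,
                   baseline_mean: float = 7.0,
                   noise_sd: float = 0.5,
                   overlap_fraction: float = 0.8,
                   seed: int = 7) -> SyntheticExpression:
    """Generate per-cultivar log2 expression matrices with planted late
    pollen-preferred genes.

    Background values are iid Normal(baseline_mean, noise_sd) on the log2
    scale; each cultivar's planted genes gain +effect_size_log2 on all of
    that cultivar's late-pollen samples. A fraction ``overlap_fraction`` of
    the planted genes is shared between cultivars; the remainder is unique
    to each. Probes per gene are 1 + Poisson(probes_per_gene_mean - 1).
    """
    if n_planted > n_genes:
        raise ValidationError("n_planted exceeds n_genes")
    if not (0.0 <= overlap_fraction <= 1.0):
        raise ValidationError("overlap_fraction must be in [0, 1]")
    if probes_per_gene_mean < 1.0:
        raise ValidationError("probes_per_gene_mean must be >= 1")
    panels = panels if panels is not None else default_panels()
    cultivars = list(panels)
    for cultivar, groups in panels.items():
        if not groups:
            raise ValidationError(f"cultivar {cultivar!r} has an empty panel")
        if not any(g.is_late_pollen for g in groups):
            raise ValidationError(
                f"cultivar {cultivar!r} panel has no late-pollen group")

    rng = np.random.default_rng(seed)
    width = len(str(n_genes))
    genes = [f"LOC_Syn{str(i + 1).zfill(width)}" for i in range(n_genes)]

    # planted sets: shared block first, then unique tails per cultivar
    n_shared = int(round(overlap_fraction * n_planted))
    n_unique = n_planted - n_shared
    needed = n_shared + n_unique * len(cultivars)
    if needed > n_genes:
        raise ValidationError("not enough genes for the requested planted sets")
    chosen = list(rng.choice(n_genes, size=needed, replace=False))
    shared = {genes[i] for i in chosen[:n_shared]}
    planted: dict[str, set[str]] = {}
    cursor = n_shared
    for cultivar in cultivars:
        unique = {genes[i] for i in chosen[cursor:cursor + n_unique]}
        cursor += n_unique
        planted[cultivar] = shared | unique

    # probes: shared across cultivars (one array platform)
    extra = rng.poisson(probes_per_gene_mean - 1.0, size=n_genes)
    probe_ids: list[str] = []
    mapping: dict[str, str] = {}
    probe_gene_idx: list[int] = []
    for gi, gene in enumerate(genes):
        for k in range(1 + int(extra[gi])):
            pid = f"{gene}.p{k + 1}"
            probe_ids.append(pid)
            mapping[pid] = gene
            probe_gene_idx.append(gi)
    probe_gene_idx = np.asarray(probe_gene_idx)

    matrices: dict[str, ExpressionMatrix] = {}
    metadata: dict[str, SampleMetadata] = {}
    for cultivar in cultivars:
        groups = panels[cultivar]
        sample_ids, records, late_cols = [], [], []
        for g in groups:
            for r in range(g.n_replicates):
                sid = f"{cultivar}_{g.tissue_group}_{g.stage_label}_r{r + 1}"
                sample_ids.append(sid)
                late_cols.append(g.is_late_pollen)
                records.append({
                    "sample_id": sid, "cultivar": cultivar,
                    "tissue_group": g.tissue_group,
                    "stage_label": g.stage_label,
                    "stage_order": g.stage_order,
                    "is_late_pollen": g.is_late_pollen,
                })
        values = rng.normal(baseline_mean, noise_sd,
                            size=(len(probe_ids), len(sample_ids)))
        late_mask = np.asarray(late_cols)
        planted_gene_idx = {genes.index(g) for g in planted[cultivar]}
        planted_probe_mask = np.isin(probe_gene_idx, list(planted_gene_idx))
        values[np.ix_(planted_probe_mask, late_mask)] += effect_size_log2
        matrices[cultivar] = ExpressionMatrix(list(probe_ids), sample_ids, values)
        metadata[cultivar] = SampleMetadata(pd.DataFrame(records))

    return SyntheticExpression(matrices, metadata, ProbeGeneMap(mapping),
                               planted, shared, genes)


def gen_go_annotation(genes: list[str],
                      planted_genes: set[str],
                      n_terms: int = 50,
                      enriched_term_fraction_in_planted: float = 0.5,
                      mean_terms_per_gene: float = 1.0,
                      background_rate: float = 0.01,
                      seed: int = 7) -> tuple[GOAnnotation, dict]:
    """GO annotation table with one designated enriched term.

    The designated term (``GO:PLANTED``) is assigned to each planted gene
    with probability ``enriched_term_fraction_in_planted`` and to every
    other gene with probability ``background_rate``; all genes additionally
    receive Poisson(mean_terms_per_gene) draws from ``n_terms`` background
    terms. Genome totals are computed from the generated table itself.
    """
    if n_terms <= 0:
        return GOAnnotation.from_pairs([]), {"enriched_term": None}
    if not (0 <= enriched_term_fraction_in_planted <= 1):
        raise ValidationError("enriched fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    terms = [f"GO:B{str(i + 1).zfill(4)}" for i in range(n_terms)]
    enriched_term = "GO:PLANTED"
    pairs: list[tuple[str, str]] = []
    planted_genes = set(planted_genes)
    for gene in genes:
        rate = (enriched_term_fraction_in_planted if gene in planted_genes
                else background_rate)
        if rng.random() < rate:
            pairs.append((gene, enriched_term))
        k = rng.poisson(mean_terms_per_gene)
        if k > 0:
            for t in rng.choice(n_terms, size=min(k, n_terms), replace=False):
                pairs.append((gene, terms[t]))
    truth = {"enriched_term": enriched_term,
             "enriched_fraction": enriched_term_fraction_in_planted,
             "background_rate": background_rate}
    return GOAnnotation.from_pairs(pairs), truth


def gen_ortholog_map(genes_a: list[str], genes_b: list[str],
                     late_a: set[str], late_b: set[str],
                     conserved_fraction: float = 0.2,
                     nonlate_ortholog_rate: float = 0.15,
                     background_ortholog_rate: float = 0.5,
                     seed: int = 7) -> tuple[OrthologMap, dict]:
    """Ortholog pairs built so that the expected conservancy of
    late_a -> late_b equals ``conserved_fraction``.

    Each late-A gene is paired with a random late-B gene with probability
    ``conserved_fraction``; otherwise, with probability
    ``nonlate_ortholog_rate``, it is paired with a random non-late B gene
    (an ortholog whose expression diverged). Non-late A genes receive
    background orthologs among non-late B genes at
    ``background_ortholog_rate``.
    """
    if not (0 <= conserved_fraction <= 1):
        raise ValidationError("conserved_fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    late_b_list = sorted(late_b)
    nonlate_b = sorted(set(genes_b) - set(late_b))
    pairs: set[tuple[str, str]] = set()
    conserved_truth: set[str] = set()
    for a in sorted(late_a):
        u = rng.random()
        if u < conserved_fraction:
            if not late_b_list:
                raise ValidationError("conserved_fraction > 0 requires a "
                                      "nonempty late_b set")
            pairs.add((a, late_b_list[int(rng.integers(len(late_b_list)))]))
            conserved_truth.add(a)
        elif u < conserved_fraction + nonlate_ortholog_rate and nonlate_b:
            pairs.add((a, nonlate_b[int(rng.integers(len(nonlate_b)))]))
    late_a_set = set(late_a)
    for a in sorted(set(genes_a) - late_a_set):
        if nonlate_b and rng.random() < background_ortholog_rate:
            pairs.add((a, nonlate_b[int(rng.integers(len(nonlate_b)))]))
    truth = {"conserved_fraction": conserved_fraction,
             "conserved_late_a": conserved_truth}
    return OrthologMap(sorted(pairs)), truth


def gen_cross_progeny(true_te_percent: float, n_progeny: int,
                      seed: int = 7,
                      cross_label: str = "HET x WT (sim)") -> CrossCounts:
    """Progeny counts from a heterozygote x wild-type cross.

    With true transmission efficiency t (as a fraction), each progeny is
    heterozygous with probability t/(1+t) and wild type with probability
    1/(1+t); homozygotes are impossible. TE = 0 gives all-wild-type progeny.
    """
    if true_te_percent < 0:
        raise ValidationError("true TE must be >= 0")
    if n_progeny <= 0:
        raise ValidationError("n_progeny must be > 0")
    t = true_te_percent / 100.0
    p_het = t / (1.0 + t)
    rng = np.random.default_rng(seed)
    n_het = int(rng.binomial(n_progeny, p_het))
    return CrossCounts(cross_label, n_progeny - n_het, n_het, 0)
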