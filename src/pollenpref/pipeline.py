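"""End-to-end synthetic-benchmark pipeline: generate, preprocess, cluster, conserve, enrich, compare, cross.

``run_all`` chains every stage over the synthetic generators with a single
seed and writes a deterministic report directory (gene lists, enrichment
table, conservancy summary, genetics table). Each stage logs its parameters
and an order-independent hash of its main output, so a run is reproducible
and auditable from the log alone.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import conservation, enrichment, genetics, orthology, preprocess, synthetic
from .io import ValidationError, write_cross_counts, write_expression

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Configuration does not validate against the documented schema."""


DEFAULT_CONFIG: dict = {
    "seed": 7,
    "synth": {
        "n_genes": 2000,
        "n_planted": 60,
        "effect_size_log2": 4.0,
        "baseline_mean": 7.0,
        "noise_sd": 0.5,
        "overlap_fraction": 0.8,
        "probes_per_gene_mean": 750 / 627,
    },
    "preprocess": {"log2": False, "quantile": True},
    "cluster": {"k": 36, "tau": 1.0, "restarts": 10, "max_iter": 300,
                "tol": 1e-6},
    "enrichment": {"p_max": 0.05, "fold_min": 2.0, "n_terms": 50,
                   "enriched_fraction": 0.5, "mean_terms_per_gene": 1.0,
                   "background_rate": 0.01},
    "orthology": {"conserved_fraction": 0.21},
    "genetics": {"true_te_percent": 85.0, "n_progeny": 60,
                 "expected_ratio": [1, 1, 0], "alpha": 0.05},
}


def validate_config(config: dict | None) -> dict:
    """Merge a user config over the defaults; unknown keys are fatal."""
    merged = json.loads(json.dumps(DEFAULT_CONFIG))
    if config is None:
        return merged
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    for section, value in config.items():
        if section == "seed":
            if not isinstance(value, int):
                raise ConfigError("seed must be an integer")
            merged["seed"] = value
            continue
        if section not in merged:
            raise ConfigError(f"unknown config section {section!r}")
        if not isinstance(value, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key, v in value.items():
            if key not in merged[section]:
                raise ConfigError(f"unknown key {section}.{key}")
            merged[section][key] = v
    return merged


@dataclass
class PipelineReport:
    """Everything ``run_all`` computes, before/while writing the report dir."""

    config: dict
    conserved: conservation.GeneSet
    per_cultivar_sets: dict[str, conservation.GeneSet]
    recovery: float                 # fraction of shared planted genes recovered
    false_discovery_rate: float     # conserved genes outside the shared truth
    enriched_rows: list[enrichment.EnrichmentRow]
    planted_term_enriched: bool
    conservancy_ab: orthology.ConservancyResult
    conservancy_ba: orthology.ConservancyResult
    transmission: list[genetics.TransmissionResult]
    truth: dict = field(default_factory=dict)


def _hash(obj) -> str:
    return hashlib.sha256(repr(obj).encode()).hexdigest()[:12]


def run_all(config: dict | None = None,
            out_dir: str | Path | None = None) -> PipelineReport:
    """Run the full synthetic benchmark and (optionally) write the report.

    Stages: synth -> preprocess -> cluster -> conserve -> enrich -> ortho ->
    genetics. Deterministic for a fixed config; per-stage sub-seeds are
    derived from the master seed.
    """
    cfg = validate_config(config)
    seed = cfg["seed"]
    rng = np.random.default_rng(seed)
    sub_seeds = {name: int(s) for name, s in zip(
        ("expression", "go", "ortho", "cross_a", "cross_b"),
        rng.integers(0, 2**31 - 1, size=5))}

    # --- stage 1: synthetic inputs ---------------------------------------
    syn = synthetic.gen_expression(seed=sub_seeds["expression"],
                                   **cfg["synth"])
    logger.info("synth: %s", {"params": cfg["synth"],
                              "hash": _hash(sorted(syn.planted_shared))})

    # --- stages 2-3: preprocess + cluster per cultivar --------------------
    per_cultivar_sets: dict[str, conservation.GeneSet] = {}
    cluster_results = {}
    for cultivar, matrix in syn.matrices.items():
        if cfg["preprocess"]["log2"]:
            matrix = preprocess.log2_transform(matrix)
        if cfg["preprocess"]["quantile"]:
            matrix = preprocess.quantile_normalize(matrix)
        averaged, group_meta = preprocess.average_replicates(
            matrix, syn.metadata[cultivar])
        ccfg = cfg["cluster"]
        result = _cluster.kmeans(averaged, K=ccfg["k"], seed=seed,
                                 n_restarts=ccfg["restarts"],
                                 max_iter=ccfg["max_iter"], tol=ccfg["tol"])
        prefs = _cluster.score_cluster_preference(result.centroids,
                                                  group_meta,
                                                  tau=ccfg["tau"])
        probes = _cluster.select_late_probes(result, prefs)
        if not probes:
            logger.warning("cultivar %s: no late-preferred clusters "
                           "(tau=%s); downstream sets will be empty",
                           cultivar, ccfg["tau"])
        gene_set = conservation.probes_to_genes(
            probes, syn.probe_gene_map, cultivar=cultivar,
            cluster_of=result.assignment)
        per_cultivar_sets[cultivar] = gene_set
        cluster_results[cultivar] = (result, prefs, averaged, group_meta)
        logger.info("cluster %s: %s", cultivar,
                    {"k": ccfg["k"], "objective": result.objective,
                     "n_late_probes": len(probes),
                     "n_late_genes": len(gene_set),
                     "hash": _hash(sorted(gene_set.locus_ids))})

    # --- stage 4: cross-cultivar conservation ----------------------------
    conserved = conservation.intersect_conserved(list(per_cultivar_sets.values()))
    shared_truth = syn.planted_shared
    recovered = conserved.locus_ids & shared_truth
    recovery = len(recovered) / len(shared_truth) if shared_truth else 0.0
    fdr = (len(conserved.locus_ids - shared_truth) / len(conserved)
           if len(conserved) else 0.0)
    logger.info("conserve: %s", {"n_conserved": len(conserved),
                                 "recovery": recovery, "fdr": fdr,
                                 "hash": _hash(sorted(conserved.locus_ids))})

    # --- stage 5: GO enrichment on the conserved set ----------------------
    ecfg = cfg["enrichment"]
    annotation, go_truth = synthetic.gen_go_annotation(
        syn.genes, planted_genes=shared_truth,
        n_terms=ecfg["n_terms"],
        enriched_term_fraction_in_planted=ecfg["enriched_fraction"],
        mean_terms_per_gene=ecfg["mean_terms_per_gene"],
        background_rate=ecfg["background_rate"], seed=sub_seeds["go"])
    if conserved.locus_ids:
        rows = enrichment.fold_enrichment(conserved.locus_ids, annotation)
        enriched_rows = enrichment.filter_enriched(
            rows, p_max=ecfg["p_max"], fold_min=ecfg["fold_min"])
    else:
        enriched_rows = []
    planted_term_hit = any(r.term_id == go_truth["enriched_term"]
                           for r in enriched_rows)
    logger.info("enrich: %s", {"n_enriched": len(enriched_rows),
                               "planted_term_enriched": planted_term_hit})

    # --- stage 6: ortholog conservancy vs a second species ----------------
    ocfg = cfg["orthology"]
    rng_b = np.random.default_rng(sub_seeds["ortho"])
    n_b = len(syn.genes)
    genes_b = [f"AT_Syn{str(i + 1).zfill(5)}" for i in range(n_b)]
    n_late_b = max(len(conserved) if len(conserved) else 1, 10)
    late_b = set(str(g) for g in rng_b.choice(genes_b, size=n_late_b,
                                              replace=False))
    query_a = (conserved.locus_ids if conserved.locus_ids
               else set(list(syn.planted_shared)))
    omap, ortho_truth = synthetic.gen_ortholog_map(
        syn.genes, genes_b, query_a, late_b,
        conserved_fraction=ocfg["conserved_fraction"],
        seed=sub_seeds["ortho"])
    set_a = conservation.GeneSet.from_loci(query_a)
    set_b = conservation.GeneSet.from_loci(late_b)
    cons_ab = orthology.conservancy(set_a, set_b, omap, "a_to_b")
    cons_ba = orthology.conservancy(set_a, set_b, omap, "b_to_a")
    logger.info("ortho: %s", {"percent_ab": cons_ab.percent_conserved,
                              "percent_ba": cons_ba.percent_conserved})

    # --- stage 7: transmission genetics -----------------------------------
    gcfg = cfg["genetics"]
    crosses = [
        synthetic.gen_cross_progeny(gcfg["true_te_percent"],
                                    gcfg["n_progeny"], seed=sub_seeds["cross_a"],
                                    cross_label="HET x WT (sim)"),
        synthetic.gen_cross_progeny(0.0, gcfg["n_progeny"],
                                    seed=sub_seeds["cross_b"],
                                    cross_label="WT x HET (sim, null allele)"),
    ]
    transmission = [genetics.analyze_cross(c, tuple(gcfg["expected_ratio"]),
                                           alpha=gcfg["alpha"])
                    for c in crosses]
    logger.info("genetics: %s", [(t.cross_label, t.te, t.distorted)
                                 for t in transmission])

    report = PipelineReport(
        config=cfg, conserved=conserved, per_cultivar_sets=per_cultivar_sets,
        recovery=recovery, false_discovery_rate=fdr,
        enriched_rows=enriched_rows, planted_term_enriched=planted_term_hit,
        conservancy_ab=cons_ab, conservancy_ba=cons_ba,
        transmission=transmission,
        truth={"planted_shared": sorted(shared_truth),
               "enriched_term": go_truth["enriched_term"],
               "conserved_late_a": sorted(ortho_truth["conserved_late_a"])})

    if out_dir is not None:
        write_report(report, Path(out_dir), syn, cluster_results, crosses)
    return report


def write_report(report: PipelineReport, out_dir: Path, syn,
                 cluster_results, crosses) -> None:
    """Write the six stage outputs as TSV/JSON under ``out_dir``."""
    out_dir.mkdir(parents=True, exist_ok=True)

    for cultivar, (result, prefs, averaged, group_meta) in cluster_results.items():
        pd.DataFrame(sorted(result.assignment.items()),
                     columns=["probe_id", "cluster"]).to_csv(
            out_dir / f"assignment_{cultivar}.tsv", sep="\t", index=False)
        pd.DataFrame(result.centroids,
                     columns=result.group_ids).to_csv(
            out_dir / f"centroids_{cultivar}.tsv", sep="\t",
            index_label="cluster")
        pd.DataFrame([(p.cluster, p.preference_index, p.is_late_preferred)
                      for p in prefs],
                     columns=["cluster", "preference_index",
                              "is_late_preferred"]).to_csv(
            out_dir / f"preference_{cultivar}.tsv", sep="\t", index=False)
        # Fig-1-style matrix: probes ordered by cluster for external heatmaps
        order = sorted(result.assignment,
                       key=lambda p: (result.assignment[p], p))
        frame = averaged.to_frame().loc[order]
        frame.insert(0, "cluster", [result.assignment[p] for p in order])
        frame.to_csv(out_dir / f"heatmap_matrix_{cultivar}.tsv", sep="\t")

    rows = []
    for locus in sorted(report.conserved.locus_ids):
        prov = report.conserved.provenance.get(locus, [])
        cultivars = sorted({c for c, _, _ in prov if c})
        clusters = sorted({k for _, k, _ in prov if k is not None})
        probes = sorted({p for _, _, ps in prov for p in ps})
        rows.append((locus, ";".join(cultivars),
                     ";".join(map(str, clusters)), ";".join(probes)))
    pd.DataFrame(rows, columns=["locus_id", "cultivars", "clusters",
                                "probes"]).to_csv(
        out_dir / "conserved_genes.tsv", sep="\t", index=False)

    enrichment.enrichment_table(report.enriched_rows).to_csv(
        out_dir / "enrichment.tsv", sep="\t", index=False)

    pd.DataFrame([
        ("A_to_B", report.conservancy_ab.n_query,
         report.conservancy_ab.n_with_ortholog,
         report.conservancy_ab.n_conserved,
         report.conservancy_ab.percent_conserved),
        ("B_to_A", report.conservancy_ba.n_query,
         report.conservancy_ba.n_with_ortholog,
         report.conservancy_ba.n_conserved,
         report.conservancy_ba.percent_conserved),
    ], columns=["direction", "n_query", "n_with_ortholog", "n_conserved",
                "percent_conserved"]).to_csv(
        out_dir / "conservancy.tsv", sep="\t", index=False)

    pd.DataFrame([(t.cross_label, c.n_wild_type, c.n_heterozygote, t.te,
                   t.chi2, t.df, t.p_value, t.distorted)
                  for t, c in zip(report.transmission, crosses)],
                 columns=["cross", "wild_type", "het", "TE", "chi2", "df",
                          "p_value", "distorted"]).to_csv(
        out_dir / "genetics.tsv", sep="\t", index=False)

    write_cross_counts(crosses, out_dir / "cross_counts.tsv")

    summary = {
        "seed": report.config["seed"],
        "n_conserved": len(report.conserved),
        "recovery_of_shared_planted": report.recovery,
        "false_discovery_rate": report.false_discovery_rate,
        "planted_term_enriched": report.planted_term_enriched,
        "conservancy_percent_a_to_b": report.conservancy_ab.percent_conserved,
        "conservancy_percent_b_to_a": report.conservancy_ba.percent_conserved,
        "transmission": [
            {"cross": t.cross_label, "TE": t.te, "chi2": t.chi2,
             "p": t.p_value, "distorted": t.distorted}
            for t in report.transmission],
    }
    (out_dir / "summary.json").write_text(json.dumps(summary, indent=2,
                                                     sort_keys=True))
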