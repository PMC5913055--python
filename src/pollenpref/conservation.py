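"""Probe-to-locus collapse and cross-cultivar intersection of late pollen-preferred sets.

Different array designs and series may tag the same locus with different
probes, so the conserved set is intersected at the gene (locus) level. By
default one late-preferred probe suffices to include a locus (the any-probe
rule); ``require_all_probes=True`` demands every probe of the locus be in
the late-preferred probe set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .io import ProbeGeneMap, ValidationError

logger = logging.getLogger(__name__)


@dataclass
class GeneSet:
    """A nonredundant set of locus ids with per-locus provenance.

    ``provenance[locus]`` is a list of (cultivar, cluster_index, probe_ids)
    tuples recording where the locus was picked up.
    """

    locus_ids: set[str]
    provenance: dict[str, list[tuple[str | None, int | None, tuple[str, ...]]]] = field(
        default_factory=dict)

    def __post_init__(self) -> None:
        self.locus_ids = set(self.locus_ids)
        for locus in self.locus_ids:
            self.provenance.setdefault(
                locus, [(None, None, ())])

    def __len__(self) -> int:
        return len(self.locus_ids)

    def __contains__(self, locus: str) -> bool:
        return locus in self.locus_ids

    @classmethod
    def from_loci(cls, loci, cultivar: str | None = None) -> "GeneSet":
        loci = set(loci)
        return cls(loci, {g: [(cultivar, None, ())] for g in loci})


def probes_to_genes(probe_set: set[str], probe_gene_map: ProbeGeneMap,
                    cultivar: str | None = None,
                    cluster_of: dict[str, int] | None = None,
                    require_all_probes: bool = False) -> GeneSet:
    """Collapse a probe set to its loci.

    A locus is included iff at least one of its probes is in ``probe_set``
    (or, with ``require_all_probes``, iff all of them are). Probes without
    a mapping are counted and logged, never fatal.
    """
    if len(probe_gene_map) == 0:
        raise ValidationError("probe-gene map is empty")
    unmapped = 0
    locus_probes: dict[str, list[str]] = {}
    for probe in sorted(probe_set):
        locus = probe_gene_map.get(probe)
        if locus is None:
            unmapped += 1
            continue
        locus_probes.setdefault(locus, []).append(probe)
    if unmapped:
        logger.info("probes_to_genes: %d of %d probes had no locus mapping",
                    unmapped, len(probe_set))

    if require_all_probes:
        probes_per_locus: dict[str, set[str]] = {}
        for p, g in probe_gene_map.mapping.items():
            probes_per_locus.setdefault(g, set()).add(p)
        locus_probes = {g: ps for g, ps in locus_probes.items()
                        if set(ps) == probes_per_locus[g]}

    provenance = {}
    for locus, probes in locus_probes.items():
        cluster = None
        if cluster_of is not None:
            clusters = sorted({cluster_of[p] for p in probes if p in cluster_of})
            cluster = clusters[0] if len(clusters) == 1 else None
            provenance[locus] = [(cultivar, cluster_of.get(p), (p,))
                                 for p in probes]
        else:
            provenance[locus] = [(cultivar, None, tuple(probes))]
    return GeneSet(set(locus_probes), provenance)


def intersect_conserved(sets: list[GeneSet]) -> GeneSet:
    """Loci present in every input set; provenance merged across inputs."""
    if len(sets) < 2:
        raise ValidationError("intersection needs at least 2 gene sets")
    common = set.intersection(*(s.locus_ids for s in sets))
    provenance: dict[str, list] = {}
    for locus in common:
        merged = []
        for s in sets:
            merged.extend(s.provenance.get(locus, []))
        provenance[locus] = merged
    return GeneSet(common, provenance)
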