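"""Tabular I/O for expression matrices, sample metadata, annotation maps and cross counts.

All tables are tab-separated UTF-8 with a mandatory header row. The
expression matrix is written probes-as-rows; the cell holding the probe-id
column header is the literal string ``probe_id``. The token ``NA`` is
accepted on input for missing expression values; downstream clustering
refuses matrices that still contain NA.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Controlled developmental-stage vocabulary (anther and pollen panels).
STAGE_VOCABULARY = (
    "PMe", "Me", "Me1", "Me2", "Me3", "ACF",
    "UG", "BG", "TG", "MP", "GP", "Fl", "other",
)

#: Stages at or after bi-cellular pollen; only these may carry the
#: late-pollen flag.
LATE_POLLEN_STAGES = frozenset({"BG", "TG", "MP", "GP"})


class ValidationError(ValueError):
    """Raised when an input table violates a structural invariant."""


@dataclass
class ExpressionMatrix:
    """Dense probes x samples matrix of (log2) intensities.

    Parameters
    ----------
    probe_ids : list of str
        Row labels; must be unique.
    sample_ids : list of str
        Column labels; must be unique.
    values : ndarray of shape (n_probes, n_samples)
        Intensities. May contain NaN (from ``NA`` tokens) until
        preprocessing eliminates them.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.probe_ids)) != len(self.probe_ids):
            dupes = _duplicates(self.probe_ids)
            raise ValidationError(f"duplicate probe ids: {sorted(dupes)[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = _duplicates(self.sample_ids)
            raise ValidationError(f"duplicate sample ids: {sorted(dupes)[:5]}")
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"value shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def has_missing(self) -> bool:
        return bool(np.isnan(self.values).any())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.probe_ids, name="probe_id"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        return cls(
            probe_ids=[str(i) for i in frame.index],
            sample_ids=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
        )


@dataclass
class SampleMetadata:
    """Per-sample annotation: cultivar, tissue group, developmental stage.

    ``is_late_pollen`` may be true only for samples whose stage label is at
    or after the bi-cellular gametophyte stage (BG, TG, MP, GP).
    """

    table: pd.DataFrame

    REQUIRED = ("sample_id", "cultivar", "tissue_group", "stage_label",
                "stage_order", "is_late_pollen")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.table.columns]
        if missing:
            raise ValidationError(f"metadata missing columns: {missing}")
        t = self.table.copy()
        t["sample_id"] = t["sample_id"].astype(str)
        t["stage_order"] = t["stage_order"].astype(int)
        t["is_late_pollen"] = t["is_late_pollen"].map(_parse_bool)
        if t["sample_id"].duplicated().any():
            dupes = t.loc[t["sample_id"].duplicated(), "sample_id"].tolist()
            raise ValidationError(f"duplicate sample_id in metadata: {dupes[:5]}")
        if (t["stage_order"] < 0).any():
            raise ValidationError("stage_order must be non-negative")
        bad = t[t["is_late_pollen"] & ~t["stage_label"].isin(LATE_POLLEN_STAGES)]
        if not bad.empty:
            raise ValidationError(
                "is_late_pollen=true requires stage_label in "
                f"{sorted(LATE_POLLEN_STAGES)}; offending samples: "
                f"{bad['sample_id'].tolist()[:5]}"
            )
        unknown = set(t["stage_label"]) - set(STAGE_VOCABULARY)
        if unknown:
            logger.info("metadata contains stage labels outside the controlled "
                        "vocabulary (accepted, cannot be late-pollen): %s",
                        sorted(unknown))
        self.table = t.reset_index(drop=True)

    def for_samples(self, sample_ids: list[str]) -> pd.DataFrame:
        """Metadata rows aligned to ``sample_ids``; errors on missing samples."""
        indexed = self.table.set_index("sample_id")
        missing = [s for s in sample_ids if s not in indexed.index]
        if missing:
            raise ValidationError(f"metadata missing for sample(s): {missing}")
        return indexed.loc[sample_ids].reset_index()


@dataclass
class ProbeGeneMap:
    """probe_id -> locus_id mapping; one probe maps to at most one locus."""

    mapping: dict[str, str]

    def __post_init__(self) -> None:
        if not isinstance(self.mapping, dict):
            self.mapping = dict(self.mapping)

    def __len__(self) -> int:
        return len(self.mapping)

    def loci(self) -> set[str]:
        return set(self.mapping.values())

    def get(self, probe_id: str) -> str | None:
        return self.mapping.get(probe_id)


@dataclass
class GOAnnotation:
    """Gene->term assignments with genome-wide assignment totals.

    The enrichment universe is term *assignments* (gene-term pairs), not
    genes: ``genome_term_repeats[t]`` counts genome-wide assignments of
    term ``t`` and ``total_genome_repeats`` is their sum.
    """

    term_to_genes: dict[str, set[str]]
    genome_term_repeats: dict[str, int]
    total_genome_repeats: int

    def __post_init__(self) -> None:
        for term, genes in self.term_to_genes.items():
            n = self.genome_term_repeats.get(term, 0)
            if n < len(genes):
                raise ValidationError(
                    f"term {term!r}: genome repeats {n} < annotated genes {len(genes)}"
                )
        total = sum(self.genome_term_repeats.values())
        if total != self.total_genome_repeats:
            raise ValidationError(
                f"total_genome_repeats {self.total_genome_repeats} != "
                f"sum of per-term repeats {total}"
            )

    @classmethod
    def from_pairs(cls, pairs: list[tuple[str, str]],
                   genome_term_repeats: dict[str, int] | None = None) -> "GOAnnotation":
        """Build from (locus_id, term_id) pairs.

        Without explicit genome totals the pair table itself is taken to be
        genome-wide.
        """
        term_to_genes: dict[str, set[str]] = {}
        counts: dict[str, int] = {}
        for locus, term in pairs:
            term_to_genes.setdefault(term, set()).add(locus)
            counts[term] = counts.get(term, 0) + 1
        repeats = genome_term_repeats if genome_term_repeats is not None else counts
        return cls(term_to_genes=term_to_genes,
                   genome_term_repeats=dict(repeats),
                   total_genome_repeats=sum(repeats.values()))


@dataclass
class OrthologMap:
    """Cross-species locus pairs; many-to-many, no duplicate pairs."""

    pairs: list[tuple[str, str]]

    def __post_init__(self) -> None:
        seen = set()
        for p in self.pairs:
            if p in seen:
                raise ValidationError(f"duplicate ortholog pair: {p}")
            seen.add(p)

    def partners_of_a(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(a, set()).add(b)
        return out

    def partners_of_b(self) -> dict[str, set[str]]:
        out: dict[str, set[str]] = {}
        for a, b in self.pairs:
            out.setdefault(b, set()).add(a)
        return out


@dataclass
class CrossCounts:
    """Progeny genotype tallies for one cross, "female x male" convention."""

    cross_label: str
    n_wild_type: int
    n_heterozygote: int
    n_homozygote: int = 0

    def __post_init__(self) -> None:
        for name in ("n_wild_type", "n_heterozygote", "n_homozygote"):
            v = getattr(self, name)
            if v < 0:
                raise ValidationError(f"{name} must be >= 0, got {v}")
            setattr(self, name, int(v))

    @property
    def total(self) -> int:
        return self.n_wild_type + self.n_heterozygote + self.n_homozygote


# ---------------------------------------------------------------------------
# readers / writers

def read_expression(matrix_path, metadata_path) -> tuple[ExpressionMatrix, SampleMetadata]:
    """Read an expression matrix and its sample metadata, cross-validated.

    Every matrix column must have exactly one metadata record; column order
    of the matrix is preserved.
    """
    frame = pd.read_csv(matrix_path, sep="\t", index_col="probe_id",
                        na_values=["NA"], keep_default_na=False)
    if frame.index.duplicated().any():
        dupes = frame.index[frame.index.duplicated()].tolist()
        raise ValidationError(f"duplicate probe id(s) in matrix: {dupes[:5]}")
    matrix = ExpressionMatrix.from_frame(frame)
    metadata = read_metadata(metadata_path)
    metadata.for_samples(matrix.sample_ids)  # raises naming missing samples
    return matrix, metadata


def write_expression(matrix: ExpressionMatrix, matrix_path) -> None:
    matrix.to_frame().to_csv(matrix_path, sep="\t", na_rep="NA")


def read_metadata(path) -> SampleMetadata:
    return SampleMetadata(pd.read_csv(path, sep="\t", dtype={"sample_id": str}))


def write_metadata(metadata: SampleMetadata, path) -> None:
    metadata.table.to_csv(path, sep="\t", index=False)


def read_probe_gene_map(path) -> ProbeGeneMap:
    t = pd.read_csv(path, sep="\t", dtype=str)
    if not {"probe_id", "locus_id"} <= set(t.columns):
        raise ValidationError("probe-gene map needs columns probe_id, locus_id")
    if t["probe_id"].duplicated().any():
        dupes = t.loc[t["probe_id"].duplicated(), "probe_id"].tolist()
        raise ValidationError(f"probe mapped to multiple loci: {dupes[:5]}")
    return ProbeGeneMap(dict(zip(t["probe_id"], t["locus_id"])))


def write_probe_gene_map(pmap: ProbeGeneMap, path) -> None:
    pd.DataFrame(sorted(pmap.mapping.items()),
                 columns=["probe_id", "locus_id"]).to_csv(path, sep="\t", index=False)


def read_go_annotation(pairs_path, totals_path=None) -> GOAnnotation:
    """Read (locus_id, term_id) pairs plus optional genome totals table."""
    t = pd.read_csv(pairs_path, sep="\t", dtype=str)
    if not {"locus_id", "term_id"} <= set(t.columns):
        raise ValidationError("annotation needs columns locus_id, term_id")
    totals = None
    if totals_path is not None:
        tt = pd.read_csv(totals_path, sep="\t", dtype={"term_id": str, "genome_repeats": int})
        totals = dict(zip(tt["term_id"], tt["genome_repeats"]))
    return GOAnnotation.from_pairs(list(zip(t["locus_id"], t["term_id"])), totals)


def write_go_annotation(annotation: GOAnnotation, pairs_path, totals_path=None) -> None:
    rows = [(g, t) for t, genes in sorted(annotation.term_to_genes.items())
            for g in sorted(genes)]
    pd.DataFrame(rows, columns=["locus_id", "term_id"]).to_csv(
        pairs_path, sep="\t", index=False)
    if totals_path is not None:
        pd.DataFrame(sorted(annotation.genome_term_repeats.items()),
                     columns=["term_id", "genome_repeats"]).to_csv(
            totals_path, sep="\t", index=False)


def read_ortholog_map(path) -> OrthologMap:
    t = pd.read_csv(path, sep="\t", dtype=str)
    if t.shape[1] < 2:
        raise ValidationError("ortholog map needs two columns (locus_a, locus_b)")
    cols = list(t.columns[:2])
    return OrthologMap(list(map(tuple, t[cols].itertuples(index=False))))


def write_ortholog_map(omap: OrthologMap, path) -> None:
    pd.DataFrame(omap.pairs, columns=["locus_a", "locus_b"]).to_csv(
        path, sep="\t", index=False)


def read_cross_counts(path) -> list[CrossCounts]:
    """Read one CrossCounts record per row; negative counts are fatal."""
    t = pd.read_csv(path, sep="\t")
    required = {"cross_label", "wild_type", "het", "hom"}
    if not required <= set(t.columns):
        raise ValidationError(f"cross-count table needs columns {sorted(required)}")
    records = []
    for row in t.itertuples(index=False):
        records.append(CrossCounts(
            cross_label=str(row.cross_label),
            n_wild_type=int(row.wild_type),
            n_heterozygote=int(row.het),
            n_homozygote=int(row.hom),
        ))
    return records


def write_cross_counts(counts: list[CrossCounts], path) -> None:
    pd.DataFrame(
        [(c.cross_label, c.n_wild_type, c.n_heterozygote, c.n_homozygote)
         for c in counts],
        columns=["cross_label", "wild_type", "het", "hom"],
    ).to_csv(path, sep="\t", index=False)


def _duplicates(items) -> set:
    seen, dupes = set(), set()
    for x in items:
        if x in seen:
            dupes.add(x)
        seen.add(x)
    return dupes


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in {"true", "1", "yes", "t"}:
        return True
    if s in {"false", "0", "no", "f"}:
        return False
    raise ValidationError(f"cannot parse boolean from {value!r}")
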