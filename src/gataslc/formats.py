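"""Genomic data containers and file I/O.

All coordinates are BED-style 0-based half-open throughout the package.
GFF3 (1-based closed) is converted at the read/write boundary and nowhere
else. Intron numbering is strand-aware: intron 1 is the first intron in
transcription order, so on a minus-strand gene it is the genomically last
gap between exons. Unknown strand (".") is ordered like "+".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import pyfaidx

__all__ = [
    "GenomicInterval",
    "GeneModel",
    "ExpressionMatrix",
    "read_bed",
    "write_bed",
    "read_gene_models",
    "write_gff3",
    "read_fasta",
    "write_fasta",
    "read_expression_table",
    "write_expression_table",
    "read_registry",
]

STRANDS = ("+", "-", ".")


class ParseError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True)
class GenomicInterval:
    """Half-open genomic interval [start, end) on ``chrom``."""

    chrom: str
    start: int
    end: int
    name: str = "."
    score: float | None = None
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end ({self.end}) must exceed start ({self.start})")
        if self.strand not in STRANDS:
            raise ValueError(f"strand must be one of {STRANDS}, got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def intersect(self, other: "GenomicInterval") -> "GenomicInterval | None":
        if not self.overlaps(other):
            return None
        return replace(self, start=max(self.start, other.start), end=min(self.end, other.end))


@dataclass(frozen=True)
class GeneModel:
    """Single-isoform gene model with explicit exon structure.

    ``exons`` are (start, end) pairs, sorted, disjoint and contained in
    [tx_start, tx_end). Introns are the gaps between consecutive exons.
    """

    gene_id: str
    chrom: str
    strand: str
    tx_start: int
    tx_end: int
    exons: tuple[tuple[int, int], ...]
    family: str | None = None

    def __post_init__(self) -> None:
        if self.strand not in STRANDS:
            raise ValueError(f"bad strand {self.strand!r} for {self.gene_id}")
        if self.tx_end <= self.tx_start:
            raise ValueError(f"{self.gene_id}: tx_end <= tx_start")
        if not self.exons:
            raise ValueError(f"{self.gene_id}: gene must have >=1 exon")
        prev_end = None
        for s, e in self.exons:
            if e <= s:
                raise ValueError(f"{self.gene_id}: empty exon [{s},{e})")
            if s < self.tx_start or e > self.tx_end:
                raise ValueError(f"{self.gene_id}: exon [{s},{e}) outside transcript")
            if prev_end is not None and s < prev_end:
                raise ValueError(f"{self.gene_id}: exons overlap or unsorted at [{s},{e})")
            prev_end = e

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        """Genomic-order intron intervals (gaps between consecutive exons)."""
        return tuple(
            (a[1], b[0]) for a, b in itertools.pairwise(self.exons) if b[0] > a[1]
        )

    def introns_by_rank(self) -> list[tuple[int, int, int]]:
        """(rank, start, end) with rank 1 = first intron in transcription order."""
        introns = self.introns
        if self.strand == "-":
            introns = introns[::-1]
        return [(i + 1, s, e) for i, (s, e) in enumerate(introns)]

    def intron_rank_at(self, pos: int) -> int | None:
        """Transcription-order rank of the intron containing ``pos``, else None."""
        for rank, s, e in self.introns_by_rank():
            if s <= pos < e:
                return rank
        return None

    def exon_at(self, pos: int) -> bool:
        return any(s <= pos < e for s, e in self.exons)

    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.tx_start, self.tx_end,
                               name=self.gene_id, strand=self.strand)


@dataclass
class ExpressionMatrix:
    """Genes x samples TPM-like expression with a sample->condition map."""

    values: pd.DataFrame  # index: gene ids, columns: sample ids
    conditions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        if self.values.isna().any().any():
            raise ValueError("expression matrix contains missing values")
        if (self.values.to_numpy() < 0).any():
            raise ValueError("expression values must be nonnegative")
        missing = [s for s in self.values.columns if s not in self.conditions]
        if missing:
            raise ValueError(f"samples missing from condition map: {missing}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    def samples_in(self, group: str) -> list[str]:
        cols = [s for s in self.values.columns if self.conditions[s] == group]
        if not cols:
            raise ValueError(f"no samples labelled {group!r}")
        return cols

    def group_values(self, group: str) -> pd.DataFrame:
        return self.values[self.samples_in(group)]


# ---------------------------------------------------------------------------
# BED

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3-6. Parsed by hand so errors carry the offending line number."""
    out: list[GenomicInterval] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ParseError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            chrom = fields[0]
            try:
                start, end = int(fields[1]), int(fields[2])
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: non-integer coordinate") from exc
            name = fields[3] if len(fields) > 3 else "."
            score: float | None = None
            if len(fields) > 4 and fields[4] not in (".", ""):
                try:
                    score = float(fields[4])
                except ValueError as exc:
                    raise ParseError(f"{path}:{lineno}: non-numeric score") from exc
            strand = fields[5] if len(fields) > 5 else "."
            try:
                out.append(GenomicInterval(chrom, start, end, name, score, strand))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write BED6; score "." when absent."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = "." if iv.score is None else format(iv.score, "g")
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.name}\t{score}\t{iv.strand}\n")


# ---------------------------------------------------------------------------
# Gene models

def read_gene_models(path: str | Path, dialect: str = "gff3") -> list[GeneModel]:
    if dialect == "gff3":
        return _read_gff3(path)
    if dialect == "bed12":
        return _read_bed12(path)
    raise ValueError(f"unknown gene-model dialect {dialect!r}")


def _read_gff3(path: str | Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes: list[GeneModel] = []
    for g in db.features_of_type("gene", order_by=("seqid", "start")):
        exons = []
        for ex in db.children(g, featuretype="exon", order_by="start"):
            exons.append((ex.start - 1, ex.end))  # 1-based closed -> half-open
        if not exons:
            exons = [(g.start - 1, g.end)]
        family = g.attributes.get("family", [None])[0]
        gene_id = g.attributes.get("ID", [g.id])[0]
        genes.append(
            GeneModel(gene_id, g.seqid, g.strand or ".", g.start - 1, g.end,
                      tuple(exons), family=family)
        )
    return genes


def _read_bed12(path: str | Path) -> list[GeneModel]:
    genes: list[GeneModel] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ParseError(f"{path}:{lineno}: BED12 needs 12 columns")
            try:
                chrom, start, end = f[0], int(f[1]), int(f[2])
                name, strand = f[3], f[5]
                sizes = [int(x) for x in f[10].rstrip(",").split(",")]
                offsets = [int(x) for x in f[11].rstrip(",").split(",")]
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: malformed BED12 field") from exc
            exons = tuple((start + o, start + o + s) for o, s in zip(offsets, sizes))
            try:
                genes.append(GeneModel(name, chrom, strand, start, end, exons))
            except ValueError as exc:
                raise ParseError(f"{path}:{lineno}: {exc}") from exc
    return genes


def write_gff3(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.tx_start, g.gene_id)):
            attrs = f"ID={g.gene_id}"
            if g.family:
                attrs += f";family={g.family}"
            fh.write(
                f"{g.chrom}\tgataslc\tgene\t{g.tx_start + 1}\t{g.tx_end}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            for i, (s, e) in enumerate(g.exons, start=1):
                fh.write(
                    f"{g.chrom}\tgataslc\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                    f"ID={g.gene_id}.exon{i};Parent={g.gene_id}\n"
                )


# ---------------------------------------------------------------------------
# FASTA

def read_fasta(path: str | Path) -> dict[str, str]:
    fa = pyfaidx.Fasta(str(path), sequence_always_upper=True, rebuild=True)
    return {name: str(fa[name][:]) for name in fa.keys()}


def write_fasta(sequences: Mapping[str, str], path: str | Path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name in sequences:
            fh.write(f">{name}\n")
            seq = sequences[name]
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Expression tables / registry

def read_expression_table(path: str | Path, condition_map: Mapping[str, str]) -> ExpressionMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if not all(pd.api.types.is_numeric_dtype(t) for t in df.dtypes):
        raise ParseError(f"{path}: non-numeric expression values")
    return ExpressionMatrix(df, dict(condition_map))


def write_expression_table(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene_id")


REGISTRY_CLASSES = ("amino acid", "metal", "nucleoside/nucleotide", "vitamin", "other")
REGISTRY_LOCALIZATIONS = ("plasma membrane", "mitochondria", "ER/Golgi", "lysosome", "unknown")


def read_registry(path: str | Path) -> pd.DataFrame:
    """Transporter registry: gene_id, family, substrate_class, localization[, phenotype]."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    required = {"gene_id", "family", "substrate_class", "localization"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: registry missing columns {sorted(missing)}")
    bad = set(df["substrate_class"]) - set(REGISTRY_CLASSES)
    if bad:
        raise ParseError(f"{path}: unknown substrate classes {sorted(bad)}")
    if df["gene_id"].duplicated().any():
        raise ParseError(f"{path}: duplicate gene ids in registry")
    if "phenotype" not in df.columns:
        df["phenotype"] = False
    df["phenotype"] = df["phenotype"].astype(bool)
    return df.set_index("gene_id", drop=False)
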