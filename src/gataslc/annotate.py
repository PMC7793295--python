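"""Peak-to-gene assignment, genomic context, and intronic enhancer calling.

A peak is assigned to every gene whose window-extended span it overlaps by
at least 1 bp. Context is single-label, decided by the midpoint of the
peak/window-span overlap: intronic (with a strand-aware intron rank),
exonic, promoter (within the window upstream of the TSS), else flanking.

A "predicted intronic enhancer" is a GATA2 ChIP peak footprint clipped to
an intron that overlaps accessible chromatin (ATAC) and contains at least
one WGATAR occurrence. GATA1 occupancy and cCRE overlap are recorded as
corroborating annotations but are not required for emission.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from intervaltree import IntervalTree

from .formats import GeneModel, GenomicInterval
from .motifs import EBOX, WGATAR, MotifHit, MotifModel, scan_motif

__all__ = [
    "PeakAssignment",
    "EnhancerCandidate",
    "assign_peaks_to_genes",
    "call_intronic_enhancers",
    "occupancy_summary",
]

CONTEXTS = ("intronic", "exonic", "promoter", "flanking")


@dataclass(frozen=True)
class PeakAssignment:
    peak: GenomicInterval
    gene_id: str
    context: str
    intron_rank: int | None = None  # set when context == "intronic"

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"bad context {self.context!r}")


def _context_for(gene: GeneModel, mid: int, window: int) -> tuple[str, int | None]:
    rank = gene.intron_rank_at(mid)
    if rank is not None:
        return "intronic", rank
    if gene.exon_at(mid):
        return "exonic", None
    tss = gene.tx_start if gene.strand != "-" else gene.tx_end - 1
    if gene.strand != "-":
        if tss - window <= mid < tss:
            return "promoter", None
    else:
        if tss < mid <= tss + window:
            return "promoter", None
    return "flanking", None


def assign_peaks_to_genes(
    peaks: Sequence[GenomicInterval],
    genes: Sequence[GeneModel],
    window: int = 10_000,
) -> list[PeakAssignment]:
    """Assign each peak to all genes within ``window`` bp of its span."""
    if window < 0:
        raise ValueError("window must be >= 0")
    trees: dict[str, IntervalTree] = {}
    by_id: dict[str, GeneModel] = {}
    for g in genes:
        trees.setdefault(g.chrom, IntervalTree()).addi(
            max(0, g.tx_start - window), g.tx_end + window, g.gene_id
        )
        by_id[g.gene_id] = g
    out: list[PeakAssignment] = []
    for peak in peaks:
        tree = trees.get(peak.chrom)
        if tree is None:
            continue
        for hit in sorted(tree.overlap(peak.start, peak.end), key=lambda h: h.data):
            g = by_id[hit.data]
            ov_start = max(peak.start, hit.begin)
            ov_end = min(peak.end, hit.end)
            mid = (ov_start + ov_end) // 2
            context, rank = _context_for(g, mid, window)
            out.append(PeakAssignment(peak, g.gene_id, context, rank))
    return out


@dataclass(frozen=True)
class EnhancerCandidate:
    gene_id: str
    intron_rank: int
    interval: GenomicInterval  # GATA2 peak footprint clipped to the intron
    gata1_occupied: bool
    gata2_occupied: bool
    accessible: bool
    ccre_overlap: bool
    wgatar_hits: tuple[MotifHit, ...]
    ebox_hits: tuple[MotifHit, ...]

    @property
    def is_predicted_enhancer(self) -> bool:
        return self.gata2_occupied and self.accessible and len(self.wgatar_hits) > 0


def _overlaps_any(iv: GenomicInterval, others: Sequence[GenomicInterval]) -> bool:
    return any(iv.overlaps(o) for o in others)


def call_intronic_enhancers(
    gata2_assignments: Sequence[PeakAssignment],
    genes: Sequence[GeneModel],
    gata1_peaks: Sequence[GenomicInterval],
    atac_peaks: Sequence[GenomicInterval],
    ccres: Sequence[GenomicInterval],
    sequences: Mapping[str, str],
    wgatar: MotifModel = WGATAR,
    ebox: MotifModel = EBOX,
) -> list[EnhancerCandidate]:
    """Build one candidate per (GATA2 peak, overlapped intron) footprint.

    A peak spanning an exon into two introns yields one candidate per
    intron footprint. Flags are set by >=1 bp overlap of the footprint
    with the respective peak set; motif scans run on the footprint
    sequence over both strands.
    """
    by_id = {g.gene_id: g for g in genes}
    seen: set[tuple[str, str, int, int]] = set()
    out: list[EnhancerCandidate] = []
    for asn in gata2_assignments:
        gene = by_id[asn.gene_id]
        peak = asn.peak
        if peak.chrom not in sequences:
            raise ValueError(f"chromosome {peak.chrom!r} missing from genome FASTA")
        for rank, istart, iend in gene.introns_by_rank():
            fs, fe = max(peak.start, istart), min(peak.end, iend)
            if fe <= fs:
                continue
            key = (gene.gene_id, peak.chrom, fs, fe)
            if key in seen:  # two GATA2 peaks can clip to the same footprint
                continue
            seen.add(key)
            footprint = GenomicInterval(peak.chrom, fs, fe,
                                        name=f"{gene.gene_id}.intron{rank}")
            seq = sequences[peak.chrom][fs:fe]
            out.append(
                EnhancerCandidate(
                    gene_id=gene.gene_id,
                    intron_rank=rank,
                    interval=footprint,
                    gata1_occupied=_overlaps_any(footprint, gata1_peaks),
                    gata2_occupied=True,
                    accessible=_overlaps_any(footprint, atac_peaks),
                    ccre_overlap=_overlaps_any(footprint, ccres),
                    wgatar_hits=tuple(scan_motif(seq, wgatar)),
                    ebox_hits=tuple(scan_motif(seq, ebox)),
                )
            )
    return sorted(out, key=lambda c: (c.interval.chrom, c.interval.start, c.gene_id))


def occupancy_summary(
    cohort: Sequence[str],
    assignments_by_assay: Mapping[str, Sequence[PeakAssignment]],
) -> pd.DataFrame:
    """Boolean gene x assay occupancy table; column sums give the marginals."""
    assays = list(assignments_by_assay)
    assigned = {
        assay: {a.gene_id for a in asns} for assay, asns in assignments_by_assay.items()
    }
    rows = {
        gene: {assay: gene in assigned[assay] for assay in assays}
        for gene in sorted(cohort)
    }
    df = pd.DataFrame.from_dict(rows, orient="index", columns=assays)
    if df.empty:
        df = pd.DataFrame(columns=assays, dtype=bool)
    df.index.name = "gene_id"
    return df.astype(bool)


def occupancy_marginals(summary: pd.DataFrame) -> pd.Series:
    """Per-assay counts of occupied genes (column sums of the summary)."""
    return summary.sum(axis=0).astype(int)


def candidates_to_frame(candidates: Sequence[EnhancerCandidate]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "chrom": c.interval.chrom,
                "start": c.interval.start,
                "end": c.interval.end,
                "intron_rank": c.intron_rank,
                "gata1_occupied": c.gata1_occupied,
                "gata2_occupied": c.gata2_occupied,
                "accessible": c.accessible,
                "ccre_overlap": c.ccre_overlap,
                "n_wgatar": len(c.wgatar_hits),
                "n_ebox": len(c.ebox_hits),
                "predicted_enhancer": c.is_predicted_enhancer,
            }
            for c in candidates
        ],
        columns=["gene_id", "chrom", "start", "end", "intron_rank",
                 "gata1_occupied", "gata2_occupied", "accessible",
                 "ccre_overlap", "n_wgatar", "n_ebox", "predicted_enhancer"],
    )
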