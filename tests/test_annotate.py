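"""Peak-to-gene assignment, context labelling and enhancer emission rules."""

import numpy as np
import pytest

from gataslc.annotate import (
    assign_peaks_to_genes,
    call_intronic_enhancers,
    occupancy_marginals,
    occupancy_summary,
)
from gataslc.formats import GeneModel, GenomicInterval
from gataslc.simulate import generate_peaks, default_config

GENE = GeneModel("g", "chr1", "+", 50, 450,
                 ((50, 100), (200, 250), (400, 450)))


def test_intronic_assignment_with_rank():
    (asn,) = assign_peaks_to_genes([GenomicInterval("chr1", 150, 160)], [GENE],
                                   window=0)
    assert asn.gene_id == "g" and asn.context == "intronic"
    assert asn.intron_rank == 1
    (asn2,) = assign_peaks_to_genes([GenomicInterval("chr1", 300, 310)], [GENE],
                                    window=0)
    assert asn2.intron_rank == 2


def test_peak_outside_window_unassigned():
    far = GenomicInterval("chr1", 60_000, 60_200)
    assert assign_peaks_to_genes([far], [GENE], window=10_000) == []
    assert len(assign_peaks_to_genes([far], [GENE], window=60_000)) == 1
    with pytest.raises(ValueError, match="window"):
        assign_peaks_to_genes([far], [GENE], window=-1)


def test_promoter_context_is_strand_aware():
    plus = GeneModel("p", "chr1", "+", 1000, 2000, ((1000, 2000),))
    minus = GeneModel("m", "chr2", "-", 1000, 2000, ((1000, 2000),))
    upstream_plus = GenomicInterval("chr1", 800, 900)
    (a,) = assign_peaks_to_genes([upstream_plus], [plus], window=500)
    assert a.context == "promoter"
    downstream_minus = GenomicInterval("chr2", 2100, 2200)
    (b,) = assign_peaks_to_genes([downstream_minus], [minus], window=500)
    assert b.context == "promoter"
    (c,) = assign_peaks_to_genes([GenomicInterval("chr2", 800, 900)], [minus],
                                 window=500)
    assert c.context == "flanking"


def _oracle_assign(peaks, genes, window):
    """Independent all-pairs reimplementation of the assignment contract."""
    out = []
    for peak in peaks:
        for g in genes:
            lo, hi = max(0, g.tx_start - window), g.tx_end + window
            if g.chrom != peak.chrom or peak.end <= lo or peak.start >= hi:
                continue
            mid = (max(peak.start, lo) + min(peak.end, hi)) // 2
            rank = g.intron_rank_at(mid)
            if rank is not None:
                ctx = "intronic"
            elif g.exon_at(mid):
                ctx, rank = "exonic", None
            else:
                tss = g.tx_start if g.strand != "-" else g.tx_end - 1
                if g.strand != "-" and tss - window <= mid < tss:
                    ctx = "promoter"
                elif g.strand == "-" and tss < mid <= tss + window:
                    ctx = "promoter"
                else:
                    ctx = "flanking"
                rank = None
            out.append((peak.chrom, peak.start, peak.end, g.gene_id, ctx, rank))
    return sorted(out)


def test_assignment_matches_allpairs_oracle():
    rng = np.random.default_rng(13)
    genes = []
    for i in range(50):
        start = int(rng.integers(0, 480_000))
        exons, pos = [], start
        for j in range(int(rng.integers(1, 5))):
            if j:
                pos += int(rng.integers(200, 900))
            ln = int(rng.integers(100, 400))
            exons.append((pos, pos + ln))
            pos += ln
        genes.append(GeneModel(f"g{i}", f"chr{1 + i % 2}",
                               str(rng.choice(["+", "-"])),
                               exons[0][0], exons[-1][1], tuple(exons)))
    peaks = []
    for i in range(1000):
        s = int(rng.integers(0, 500_000))
        peaks.append(GenomicInterval(f"chr{1 + int(rng.integers(2))}", s,
                                     s + int(rng.integers(50, 600)), f"p{i}"))
    got = sorted(
        (a.peak.chrom, a.peak.start, a.peak.end, a.gene_id, a.context,
         a.intron_rank)
        for a in assign_peaks_to_genes(peaks, genes, window=5_000)
    )
    assert got == _oracle_assign(peaks, genes, 5_000)


SEQ = {"chr1": "C" * 1000}


def planted_seq():
    s = list(SEQ["chr1"])
    s[150:156] = "TGATAA"  # inside intron 1 of GENE
    return {"chr1": "".join(s)}


def test_enhancer_emission_rule_and_flags():
    peak = GenomicInterval("chr1", 140, 180, name="pk")
    asn = assign_peaks_to_genes([peak], [GENE], window=0)
    atac = [GenomicInterval("chr1", 100, 200)]
    cands = call_intronic_enhancers(asn, [GENE], [], atac, [], planted_seq())
    (c,) = cands
    assert c.is_predicted_enhancer
    assert c.accessible and c.gata2_occupied and not c.gata1_occupied
    assert len(c.wgatar_hits) == 1

    # same peak without ATAC: candidate retained, not emitted
    cands = call_intronic_enhancers(asn, [GENE], [], [], [], planted_seq())
    (c,) = cands
    assert not c.accessible and not c.is_predicted_enhancer

    # accessible but motif-free footprint: not emitted
    cands = call_intronic_enhancers(asn, [GENE], [], atac, [], SEQ)
    assert not cands[0].is_predicted_enhancer


def test_emission_monotone_in_atac_peaks():
    peak = GenomicInterval("chr1", 140, 180)
    asn = assign_peaks_to_genes([peak], [GENE], window=0)
    seqs = planted_seq()
    atac_sets = ([], [GenomicInterval("chr1", 0, 10)],
                 [GenomicInterval("chr1", 0, 10), GenomicInterval("chr1", 150, 151)])
    emitted = [
        {c.interval for c in call_intronic_enhancers(asn, [GENE], [], atac, [], seqs)
         if c.is_predicted_enhancer}
        for atac in atac_sets
    ]
    assert emitted[0] <= emitted[1] <= emitted[2]


def test_candidate_clipped_to_intron_and_split_across_introns():
    # peak spans intron1, exon2 and intron2: one candidate per intron footprint
    peak = GenomicInterval("chr1", 180, 320)
    asn = assign_peaks_to_genes([peak], [GENE], window=0)
    cands = call_intronic_enhancers(asn, [GENE], [], [], [], SEQ)
    assert [(c.interval.start, c.interval.end) for c in cands] == [(180, 200), (250, 320)]
    assert [c.intron_rank for c in cands] == [1, 2]
    for c in cands:
        assert c.interval.length <= peak.length
        introns = dict((r, (s, e)) for r, s, e in GENE.introns_by_rank())
        s, e = introns[c.intron_rank]
        assert s <= c.interval.start and c.interval.end <= e


def test_missing_chromosome_errors():
    peak = GenomicInterval("chrX", 140, 180)
    gene = GeneModel("x", "chrX", "+", 50, 450, ((50, 100), (200, 450)))
    asn = assign_peaks_to_genes([peak], [gene], window=0)
    with pytest.raises(ValueError, match="chrX"):
        call_intronic_enhancers(asn, [gene], [], [], [], SEQ)


def test_occupancy_summary_and_marginals(synthetic_genome):
    sequences, genes, truth = synthetic_genome
    cfg = default_config(seed=5)
    gata1, gata2, atac, ccre = generate_peaks(genes, truth, cfg)
    asn = {name: assign_peaks_to_genes(pk, genes, 10_000)
           for name, pk in (("GATA1", gata1), ("GATA2", gata2),
                            ("ATAC", atac), ("cCRE", ccre))}
    cohort = [g.gene_id for g in genes]
    table = occupancy_summary(cohort, asn)
    # brute-force recomputation from raw overlaps (window-extended spans)
    for g in genes:
        for name, pk in (("GATA1", gata1), ("GATA2", gata2)):
            expected = any(
                p.chrom == g.chrom and p.start < g.tx_end + 10_000
                and p.end > g.tx_start - 10_000 for p in pk
            )
            assert bool(table.at[g.gene_id, name]) == expected
    marg = occupancy_marginals(table)
    assert (marg == table.sum(axis=0)).all()
    # genes with no assignments give an all-false row
    planted = {p.gene_id for p in truth.planted_peaks}
    decoy = next(g.gene_id for g in genes if g.gene_id not in planted)
    assert not table.loc[decoy].any()
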