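"""IUPAC scanning, matched-background sampling and the permutation test."""

import numpy as np
import pytest

from gataslc.formats import GeneModel, GenomicInterval
from gataslc.motifs import (
    EBOX,
    IUPAC,
    WGATAR,
    IntronSpace,
    MotifIndex,
    MotifModel,
    group_statistic,
    permutation_test,
    reverse_complement,
    sample_matched_background,
    scan_motif,
)

# ------------------------------------------------------------------ scanning


def test_wgatar_forward_and_reverse_hits():
    hits = scan_motif("TGATAA", WGATAR)
    assert [(h.offset, h.strand) for h in hits] == [(0, "+")]
    # TTATCA is the reverse complement of TGATAA
    hits = scan_motif("TTATCA", WGATAR)
    assert [(h.offset, h.strand) for h in hits] == [(0, "-")]
    assert scan_motif("ttatca", WGATAR) == scan_motif("TTATCA", WGATAR)


def test_ebox_is_palindromic_and_not_double_counted():
    assert EBOX.is_palindromic and not WGATAR.is_palindromic
    hits = scan_motif("CAGCTG", EBOX)
    assert [(h.offset, h.strand) for h in hits] == [(0, "+")]


def test_n_in_sequence_never_matches():
    assert scan_motif("TGANAA", WGATAR) == []
    assert scan_motif("NNNNNN", WGATAR) == []


def test_overlapping_occurrences_all_reported():
    # AGATAGATAG: AGATAG at 0 and 4 overlap
    hits = [h for h in scan_motif("AGATAGATAG", WGATAR) if h.strand == "+"]
    assert [h.offset for h in hits] == [0, 4]


def test_motif_model_validation():
    with pytest.raises(ValueError, match="invalid IUPAC"):
        MotifModel("bad", "WGAXAR")
    with pytest.raises(ValueError, match=">=4"):
        MotifModel("short", "ACG")


def _naive_scan(seq, motif):
    """Position-by-position sliding-window oracle."""
    seq = seq.upper()
    k = len(motif.iupac)
    hits = []
    for pattern, strand in ((motif.iupac, "+"), (motif.rc_iupac, "-")):
        if strand == "-" and motif.is_palindromic:
            continue
        for i in range(len(seq) - k + 1):
            if all(seq[i + j] in IUPAC[pattern[j]] for j in range(k)):
                hits.append((i, strand))
    return sorted(hits)


@pytest.mark.parametrize("motif", [WGATAR, EBOX, MotifModel("x", "RYSWKM")])
def test_scan_matches_naive_oracle_on_random_sequences(motif):
    rng = np.random.default_rng(17)
    for _ in range(500):
        seq = "".join(rng.choice(list("ACGTN"), p=[0.24, 0.24, 0.24, 0.24, 0.04],
                                 size=200))
        got = sorted((h.offset, h.strand) for h in scan_motif(seq, motif))
        assert got == _naive_scan(seq, motif)


def test_group_statistic_modes():
    seqs = ["TGATAA" + "C" * 10, "C" * 16, "TGATAACCCCTTATCA"]
    assert group_statistic(seqs, WGATAR) == 2
    assert group_statistic(seqs, WGATAR, "count") == 3
    assert group_statistic(["C" * 8] * 3, WGATAR) == 0
    assert group_statistic(["TGATAA"] * 4, WGATAR) == 4
    with pytest.raises(ValueError, match="nonempty"):
        group_statistic([], WGATAR)


def test_group_statistic_strand_symmetric():
    rng = np.random.default_rng(23)
    seqs = ["".join(rng.choice(list("ACGT"), size=300)) for _ in range(10)]
    rc = [reverse_complement(s) for s in seqs]
    for motif in (WGATAR, EBOX):
        assert group_statistic(seqs, motif) == group_statistic(rc, motif)
        assert group_statistic(seqs, motif, "count") == \
            group_statistic(rc, motif, "count")


# ------------------------------------------------------------------ sampler


def toy_genome():
    seq = {"chr1": "ACGT" * 2500, "chr2": "GGCC" * 2500}
    genes = [
        GeneModel("gA", "chr1", "+", 100, 5000,
                  ((100, 200), (1200, 1300), (4800, 5000))),
        GeneModel("gB", "chr2", "+", 0, 4000, ((0, 100), (3800, 4000))),
    ]
    return seq, genes


def test_background_sampler_contracts():
    seq, genes = toy_genome()
    rng = np.random.default_rng(5)
    observed = [("chr1", 300), ("chr2", 1000), ("chr1", 900)]
    out = sample_matched_background(observed, genes, seq, rng)
    assert [len(s) for s in out] == [300, 1000, 900]
    # resample placements to check interval containment
    space = IntronSpace(genes)
    rng2 = np.random.default_rng(5)
    for (chrom, length), s in zip(observed, out):
        a, b = space.sample_placement(chrom, length, rng2)
        assert space.contains(chrom, a, b)
        assert seq[chrom][a:b] == s


def test_background_sampler_error_names_item():
    seq, genes = toy_genome()
    with pytest.raises(ValueError, match="item 1 .*chr2, 5000"):
        sample_matched_background([("chr1", 100), ("chr2", 5000)], genes, seq,
                                  np.random.default_rng(0))


def test_sampler_is_uniform_over_placements():
    # one chromosome, two eligible introns of unequal placement counts
    seq = {"c": "A" * 2000}
    genes = [GeneModel("g", "c", "+", 0, 2000,
                       ((0, 10), (110, 120), (1020, 2000)))]
    # introns: [10,110) length 100 -> 91 placements of len 10;
    # [120,1020) length 900 -> 891 placements
    space = IntronSpace(genes)
    rng = np.random.default_rng(1)
    n = 20_000
    first = sum(space.sample_placement("c", 10, rng)[0] < 120 for _ in range(n))
    frac = first / n
    expect = 91 / (91 + 891)
    assert abs(frac - expect) < 0.01


def test_motif_index_agrees_with_direct_scan():
    rng = np.random.default_rng(3)
    seq = {"c": "".join(rng.choice(list("ACGT"), size=20_000))}
    idx = MotifIndex(seq, WGATAR)
    for _ in range(200):
        s = int(rng.integers(0, 19_000))
        e = s + int(rng.integers(10, 900))
        assert idx.count_in("c", s, e) == len(scan_motif(seq["c"][s:e], WGATAR))


# ---------------------------------------------------------------- perm test


def test_saturating_pattern_gives_p_one():
    seq, genes = toy_genome()
    observed = [GenomicInterval("chr1", 500, 600)]
    res = permutation_test(observed, genes, seq, MotifModel("any", "NNNN"),
                           n_iter=50, seed=1)
    assert res.observed_statistic == 1
    assert res.p_empirical == 1.0


def test_motif_free_observed_gives_p_one():
    seq = {"c": "C" * 10_000}
    genes = [GeneModel("g", "c", "+", 0, 10_000,
                       ((0, 10), (5000, 10_000)))]
    res = permutation_test([GenomicInterval("c", 100, 300)], genes, seq,
                           WGATAR, n_iter=30, seed=2)
    assert res.observed_statistic == 0
    assert res.p_empirical == 1.0


@pytest.mark.parametrize("n_iter", [19, 99, 400])
def test_constructed_null_floor_p_value(n_iter):
    # introns are motif-free; the observed (extragenic) window carries a
    # planted site, so no null draw can reach the observed statistic
    base = list("C" * 12_000)
    base[10_500:10_506] = "TGATAA"  # outside the gene span
    seq = {"c": "".join(base)}
    genes = [GeneModel("g", "c", "+", 0, 9000, ((0, 10), (8900, 9000)))]
    res = permutation_test([GenomicInterval("c", 10_450, 10_550)], genes, seq,
                           WGATAR, n_iter=n_iter, seed=3)
    assert res.observed_statistic == 1
    assert res.p_empirical == 0.0
    assert res.p_corrected == pytest.approx(1 / (n_iter + 1))


def test_permutation_reproducible_and_histogram_complete():
    rng = np.random.default_rng(9)
    seq = {"chr1": "".join(rng.choice(list("ACGT"), size=10_000)),
           "chr2": "".join(rng.choice(list("ACGT"), size=10_000))}
    genes = [
        GeneModel("gA", "chr1", "+", 100, 5000,
                  ((100, 200), (1200, 1300), (4800, 5000))),
        GeneModel("gB", "chr2", "+", 0, 4000, ((0, 100), (3800, 4000))),
    ]
    observed = [GenomicInterval("chr1", 1500, 1700),
                GenomicInterval("chr2", 200, 500)]
    a = permutation_test(observed, genes, seq, WGATAR, n_iter=200, seed=42)
    b = permutation_test(observed, genes, seq, WGATAR, n_iter=200, seed=42)
    assert np.array_equal(a.null_counts, b.null_counts)
    assert a.p_empirical == b.p_empirical
    assert a.null_counts.sum() == 200
    c = permutation_test(observed, genes, seq, WGATAR, n_iter=200, seed=43)
    assert not np.array_equal(a.null_counts, c.null_counts)


def test_planting_motifs_never_raises_p(synthetic_genome):
    sequences, genes, truth = synthetic_genome
    enhancers = [p.interval() for p in truth.enhancers]
    weak = enhancers[:4]   # fewer motif-bearing observed sequences
    strong = enhancers
    r_weak = permutation_test(weak, genes, sequences, WGATAR,
                              n_iter=300, seed=7)
    r_strong = permutation_test(strong, genes, sequences, WGATAR,
                                n_iter=300, seed=7)
    # all planted sequences carry WGATAR: stat saturates in both groups
    assert r_weak.observed_statistic == len(weak)
    assert r_strong.observed_statistic == len(strong)
    assert r_strong.p_empirical <= 0.05


def test_permutation_input_validation():
    seq, genes = toy_genome()
    with pytest.raises(ValueError, match="n_iter"):
        permutation_test([GenomicInterval("chr1", 0, 10)], genes, seq, WGATAR,
                         n_iter=0)
    with pytest.raises(ValueError, match="empty"):
        permutation_test([], genes, seq, WGATAR)
    with pytest.raises(ValueError, match="missing"):
        permutation_test([GenomicInterval("chrZ", 0, 10)], genes, seq, WGATAR,
                         n_iter=5)
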