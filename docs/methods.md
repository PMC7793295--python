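# Methods

## Coordinate and annotation conventions

All internal coordinates are BED-style 0-based half-open; GFF3 (1-based
closed) is converted at the read/write boundary only. Intron numbering is
strand-aware: intron 1 is the first intron in transcription order, so on a
minus-strand gene it is the genomically last inter-exon gap. Unknown
strand (".") is ordered like "+", giving deterministic behaviour for
minimal inputs. Gene models are single-isoform: the intron logic used
throughout (first-intron enhancers, matched intronic backgrounds) needs
only one exon chain per gene.

## Differential regulation

For each contrast, log2 FC = log2((mean_b + pc)/(mean_a + pc)) with
pseudocount pc = 0.5 TPM (needed for zero-expression genes; the estimate
is therefore mildly shrunk toward 0 for genes expressed near or below
1 TPM). Significance is an unpaired two-tailed Student's t test on
log2(TPM + pc), followed by Benjamini–Hochberg FDR across all genes of
the matrix; Welch's unequal-variance variant is available as an option
but is measurably conservative at n = 3 per group (simulated type-I
≈ 0.035 at α = 0.05 versus 0.05 for Student's t under the homoscedastic
log-normal noise model), so the equal-variance test is the default.
Degenerate cases: with fewer than two replicates per group p is set to 1
and flagged untested; when both groups are exactly constant, p is 1 if
the means agree and 0 otherwise (perfect separation). Genes with both
condition means below the pseudocount are dropped before the FDR pass
("not expressed in the system").

A gene is called regulated when max(FC, 1/FC) ≥ 1.5 (inclusive) and
FDR ≤ 0.05; both thresholds are config-exposed. Direction is reported as
the factor's action: in the GATA1 induction system "activated" means up
upon induction; in the GATA2 enhancer-mutant system "activated" means
down in the mutant relative to wild type (the factor normally sustains
the gene). The choice of test and FDR level behind "statistically
significant" is a defensible stand-in and is deliberately configurable.

## Cohort partition and enrichment

The Venn partition is exact set algebra on gene ids; conflicting duplicate
calls for one factor are an error. Direction groups key the co-regulated
set by (GATA2 direction, GATA1 direction). Substrate-class enrichment
compares a cohort against the full transporter registry (456-member
ensemble analogue) with a 2×2 Pearson chi-square, 1 df, no continuity
correction. The Pearson statistic is always reported; when any expected
cell is below 5 the p-value switches to Fisher's exact test and the
output says so. Classes are single-label per gene; the ensemble
denominator is the whole registry by default (an expressed-only
denominator is a flag).

## Peak assignment and enhancer calling

A peak is assigned to every gene whose span, extended by a window
(default 10 kb per side, config-exposed; no explicit peak-to-gene rule
exists upstream, occupancy being read from browser tracks), it overlaps
by ≥ 1 bp. Context is single-label, decided by the midpoint of the
peak/window-span overlap, checked intron-first (ties at exon/intron
junctions resolve intronic by the half-open convention); promoter means
within the window upstream of the strand-aware TSS.

A predicted intronic enhancer is a GATA2 peak footprint clipped to an
intron (one candidate per overlapped intron for peaks spanning several)
that overlaps an ATAC peak and contains ≥ 1 WGATAR occurrence on either
strand. GATA1 occupancy, cCRE overlap and E-box hits are annotations,
not requirements: the emission rule is one consistent reading of a
narratively described criterion and is config-exposed. Emission is
monotone in the ATAC set: adding accessible intervals can only add
predicted enhancers.

## Motif scanning

Motifs are IUPAC strings (WGATAR = [A/T]GATA[A/G]; E-box = CANNTG),
compiled to overlapping-match regexes. Both strands are scanned — GATA
factors bind double-stranded sites — with reverse-strand hits reported
in forward coordinates. An N in the sequence never matches. If a pattern
equals its own reverse complement (CANNTG does), only the forward strand
is scanned, so no site is reported twice at the same interval.

## Matched-background permutation test

Observed intervals (the predicted enhancer footprints) are tested for
motif enrichment against random intronic sequence matched per item for
length and chromosome: each null draw is uniform over all (intron,
offset) placements of the observed length on the same chromosome,
sampled with replacement across items and iterations (10,000 iterations
by default). "Same chromosome, any intron" is the weakest reading of
"similar chromosomal location"; a distance-band restriction is left to
the configuration surface. Backgrounds draw on all genes' introns, not
only SLC genes. The group statistic is the number of sequences
containing ≥ 1 hit ("presence"); a total-occurrence "count" statistic is
a switch. Both the plain proportion p = #{S_null ≥ S_obs}/N and the
add-one-corrected (k+1)/(N+1) are reported; the plain proportion is the
headline number, the corrected form is the one to threshold on.

Null evaluation is accelerated by a chromosome-wide index of motif hit
starts (two bisections per interval instead of a rescan); equality with
direct scanning is itself under test.

Calibration: with the presence statistic on groups of eight, the null
support has only nine values, so the empirical p is intrinsically
conservative (analytically, a rejection rate near 0.016 at α = 0.05 for
typical per-sequence hit probabilities). The calibration suite therefore
exercises the count statistic on 1 kb items, whose ~Poisson(15) null
support is fine enough for the corrected p to be near-exact; the
observed rejection rate under the null is required to fall in the 99%
binomial band around 0.05. This conservatism is a general property of
heavily tied permutation statistics, not of this implementation.

## Prioritization

Magnitude ranking (`rank_top_k`) sorts one factor's calls of one
direction by fold-change magnitude, ties alphabetical. The candidate
score is a transparent linear stand-in for an unspecified upstream
scoring scheme: score = w_fc·log2(FC magnitude) + Σ w_flag·flag over
{GATA1 occupied, GATA2 occupied, accessible, cCRE, has intronic
enhancer, phenotype annotation}, defaults w_fc = 1, flags 1, phenotype 2.
Candidates are restricted to the co-regulated cohort; the fold magnitude
of a shared gene is the larger of its two per-factor magnitudes;
ordering is score, then fold magnitude, then gene id. Phenotype enters
as a boolean registry column, not free text.

## Synthetic data generator

The generator emulates the study conditions: two chromosomes of 800 kb,
40 genes (2–8 exons, exons 150–400 bp, introns 500–1500 bp, uniform 25%
base composition so analytic motif-occurrence expectations are exact:
WGATAR starts at 2·4/4⁶ ≈ 0.00195/bp over both strands), half labelled
SLC. Eight SLC genes host planted accessible intronic enhancers —
a GATA2 peak interval (150–400 bp) containing a substituted WGATAR
instance (and an E-box, placed clear of it), covered by ATAC and cCRE
intervals, plus GATA1 co-occupancy — and nine further SLC genes carry
GATA2/GATA1 intronic peaks in closed chromatin, mirroring the
8-of-17 occupied-cohort structure. Planted expression effects (log2
1–3 in factor-action orientation) make the 17 co-regulated; three more
genes are singly regulated; the rest are nulls. Decoy peaks for all four
assays sit in intergenic space with > 10 kb clearance from any
transcript, so decoy genes acquire no assignments at the default window.

Expression: baseline log2 TPM ~ N(5, 2) floored at 1 (planted regulated
genes are expressed genes; without the floor the pseudocount shrinks
near-threshold fold estimates on sub-TPM genes below the 1.5 criterion),
condition-2 means multiplied by 2^(±effect) with the per-system sign,
homoscedastic N(0, noise_sd) replicate noise in log2 space (default
0.5), n = 3 per condition. Gene identity (which ids are SLC, hosts,
occupied-only) is deterministic by construction; all randomness flows
from the config seed, and byte-identical outputs for identical
(config, seed) are under test.

What the generator does not emulate — and hence what passing tests do
not show about real data: read-level noise and mappability, correlated
or heavy-tailed expression noise, ChIP signal shape and peak-calling
uncertainty, non-uniform genomic base composition and repeat structure,
multi-isoform genes. The planted-truth closure results (exact recovery
of regulated sets and enhancers at zero noise) validate the pipeline's
logic, not its robustness to those artifacts.

## Pipeline and reproducibility

One global seed is expanded into per-stage substreams by seeding numpy's
generator with [seed, stage-tag], so stages rerun in isolation reproduce
their in-pipeline results. All thresholds (1.5, 0.05, 0.5, 10 kb,
10,000, 456) live in the config, never in code. The end-to-end summary
is byte-identical across reruns with the same config.

Problem sizes used by the test and acceptance suites — 40-gene/1.6 Mb
synthetic genomes, 2,000-gene null contrasts, 1,000 calibration
repetitions at 500 iterations each, 10,000-iteration enrichment tests —
were chosen to make every statistical check well-powered at desk scale
while the full suite stays fast.
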