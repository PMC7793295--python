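# gataslc

Identification, partitioning and prioritization of GATA-factor-regulated
solute-carrier (SLC) transporter genes in erythroid cells, as a tested,
reusable pipeline.

## The problem

GATA1 and GATA2 are zinc-finger transcription factors that drive erythroid
differentiation; during maturation GATA1 replaces GATA2 at shared target
sites (the "GATA switch"). The ~456-member SLC family establishes the small
molecule constitution of cells, and which SLC transporters are under GATA
control — and through which regulatory elements — is a question that
integrates several data types:

- two replicate expression contrasts (TPM units): an estradiol-inducible
  GATA1 rescue line (untreated vs induced) and wild-type vs
  *Gata2*-enhancer-mutant erythroid precursors;
- GATA1/GATA2 ChIP-seq peaks, ATAC-seq accessible-chromatin intervals and
  candidate cis-regulatory elements (cCREs);
- genome sequence and gene models, for intron-aware peak annotation and
  motif scanning.

The pipeline turns these into: per-factor regulated-gene calls at a
fold-change threshold (|FC| ≥ 1.5, BH-FDR ≤ 0.05 on a two-tailed Student's
t test of log2(TPM + 0.5)); a Venn partition into GATA1-only / GATA2-only /
co-regulated cohorts with four-way direction groups keyed
(GATA2 direction, GATA1 direction); substrate-class enrichment of cohorts
against the full transporter registry (Pearson chi-square, 1 df, Fisher's
exact p when an expected cell < 5); *predicted intronic enhancers* — GATA2
peak footprints clipped to introns that overlap ATAC peaks and contain at
least one WGATAR ([A/T]GATA[A/G]) occurrence, with GATA1/cCRE/E-box
(CANNTG) annotations; a matched-background permutation test for motif
enrichment in those footprints; and an evidence-weighted candidate ranking.

The permutation test is the statistical core: for a group of *n* observed
intronic intervals it draws, in each of 10,000 iterations, *n* random
intronic placements matched for length and chromosome, recomputes the group
statistic *S* = #{sequences with ≥ 1 motif hit} (or the total occurrence
count), and reports p = #{S_null ≥ S_obs}/10,000 together with the add-one
corrected (k+1)/(N+1) form.

Because the public datasets behind the original analysis are not shipped,
the package includes a first-class synthetic-data generator that emulates
the study's statistical structure — planted fold changes in both contrasts,
planted accessible WGATAR/E-box intronic enhancers under GATA2 peaks,
occupied-but-closed decoy peaks, intergenic decoy peaks and null genes —
with exact ground truth, so every stage is testable end to end.

## Worked example

Run the full pipeline on a noiseless synthetic dataset (17 GATA2-occupied
SLC genes, 8 of them carrying planted accessible intronic enhancers):

```bash
gataslc run-all --config demo.yaml --outdir out/
# demo.yaml:  seed: 7 / n_iter: 10000 / noise_sd: 0.0
```

prints (abridged):

```
key                   value
g1_only               2
g2_only               1
shared                17
g2_up/g1_down         12
g2_up/g1_up           5
predicted_enhancers   8
perm_p_wgatar         0.0003
perm_p_ebox           0.0162
top_genes             g0004,g0000,g0005,g0001,g0003,g0002,g0006,g0007,...
```

Reading: 17 genes are co-regulated by both factors (12 GATA2-activated/
GATA1-repressed, 5 activated by both); exactly the 8 planted enhancers are
recovered as predicted intronic enhancers; WGATAR and E-box motifs are
enriched in those footprints relative to length- and chromosome-matched
random intronic sequence (empirical p over 10,000 null groups); and the 8
enhancer-bearing genes occupy the top 8 ranks of the evidence-weighted
candidate list. Per-stage tables (fold changes, calls, partition,
enrichment, occupancy, candidates, null histograms) land in `out/`.

The same stages run on real files via the `simulate`, `de`, `partition`,
`integrate`, `motif-test` subcommands (BED/GFF3/FASTA/TSV in, TSV/BED out);
see `gataslc --help`.

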