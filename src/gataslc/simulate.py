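"""Synthetic genome, expression and peak-set generator with planted truth.

The generator emulates the statistical structure of the study system: two
replicate expression contrasts (an estradiol-inducible GATA1 rescue line,
untreated vs induced; and wild-type vs enhancer-mutant GATA2 erythroid
precursors), GATA ChIP / ATAC / cCRE peak sets, and intronic enhancer
sequences carrying WGATAR / E-box motifs — plus decoy genes and decoy
intergenic peaks with no signal.

Planted effects are expressed in *factor-action* orientation: a positive
log2 effect means the factor activates the gene. The contrast matrices
apply the correct sign per system (GATA1 activation appears as an increase
upon induction; GATA2 activation appears as a *decrease* in the
enhancer-mutant relative to wild type).

Gene identity is deterministic by construction: gene ids are ``g0000``,
``g0001``, ...; SLC-family labels go to the first ``round(fraction_slc *
n_genes)`` ids; enhancer hosts are the first SLC ids and occupied-only
genes the next ones. Randomness (structure, sequence, noise, peak decoys)
is fully controlled by the config seed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .formats import (
    ExpressionMatrix,
    GeneModel,
    GenomicInterval,
    write_bed,
    write_expression_table,
    write_fasta,
    write_gff3,
)

__all__ = [
    "SyntheticConfig",
    "PlantedPeak",
    "GroundTruth",
    "default_config",
    "generate_genome",
    "generate_expression",
    "generate_peaks",
    "make_registry",
    "write_all",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")

# gene-structure bounds; MAX_GENE_SPAN follows from them
MIN_EXONS, MAX_EXONS = 2, 8
EXON_LEN = (150, 400)
INTRON_LEN = (500, 1500)
MAX_GENE_SPAN = MAX_EXONS * EXON_LEN[1] + (MAX_EXONS - 1) * INTRON_LEN[1]
GENE_OFFSET = 4_000          # transcript start offset within its slot
DECOY_CLEARANCE = 10_001     # decoy peaks stay this far from any transcript
MIN_SLOT = GENE_OFFSET + MAX_GENE_SPAN + 2 * DECOY_CLEARANCE + 1_000


@dataclass
class SyntheticConfig:
    """Study-condition parameters for the synthetic generator."""

    n_chromosomes: int = 2
    chrom_length: int = 800_000
    n_genes: int = 40
    fraction_slc: float = 0.5
    n_planted_enhancers: int = 8
    n_occupied_only: int = 9          # intronic GATA2 peak, closed chromatin
    planted_log2fc_gata1: dict[str, float] = field(default_factory=dict)
    planted_log2fc_gata2: dict[str, float] = field(default_factory=dict)
    n_replicates: int = 3
    noise_sd: float = 0.5             # log2-scale replicate noise
    baseline_log2_mean: float = 5.0   # log2 TPM of baseline means
    baseline_log2_sd: float = 2.0
    peak_width: tuple[int, int] = (150, 400)
    plant_ebox: bool = True
    n_decoy_peaks: int = 30           # intergenic decoys per assay
    # expected WGATAR starts per bp under uniform base composition, both strands
    motif_density_background: float = 2 * 4 / 4096
    ensemble_size: int = 456
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_chromosomes", "chrom_length", "n_genes", "n_replicates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be positive")
        if not 0 < self.fraction_slc <= 1:
            raise ValueError("fraction_slc must be in (0, 1]")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.peak_width[0] > self.peak_width[1] or self.peak_width[0] < 10:
            raise ValueError("peak_width must be (min, max) with min >= 10")
        n_slc = round(self.fraction_slc * self.n_genes)
        if self.n_planted_enhancers + self.n_occupied_only > n_slc:
            raise ValueError("not enough SLC-labelled genes for planted peaks")

    # -- deterministic identity ------------------------------------------
    @property
    def gene_ids(self) -> list[str]:
        return [f"g{i:04d}" for i in range(self.n_genes)]

    @property
    def slc_ids(self) -> list[str]:
        return self.gene_ids[: round(self.fraction_slc * self.n_genes)]

    @property
    def enhancer_host_ids(self) -> list[str]:
        return self.slc_ids[: self.n_planted_enhancers]

    @property
    def occupied_only_ids(self) -> list[str]:
        k = self.n_planted_enhancers
        return self.slc_ids[k : k + self.n_occupied_only]


@dataclass(frozen=True)
class PlantedPeak:
    """A GATA2-occupied intronic interval planted in a host gene."""

    gene_id: str
    chrom: str
    start: int
    end: int
    intron_rank: int
    motifs: tuple[str, ...]
    accessible: bool
    gata1_occupied: bool
    ccre: bool

    @property
    def is_enhancer(self) -> bool:
        return self.accessible and "WGATAR" in self.motifs

    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end,
                               name=f"{self.gene_id}.planted")


@dataclass
class GroundTruth:
    """Planted regulatory truth for a synthetic dataset."""

    log2fc_gata1: dict[str, float]   # factor-action orientation
    log2fc_gata2: dict[str, float]
    planted_peaks: list[PlantedPeak]

    def direction(self, factor: str, gene_id: str) -> str | None:
        table = self.log2fc_gata1 if factor == "GATA1" else self.log2fc_gata2
        lfc = table.get(gene_id, 0.0)
        if lfc > 0:
            return "activated"
        if lfc < 0:
            return "repressed"
        return None

    @property
    def enhancers(self) -> list[PlantedPeak]:
        return [p for p in self.planted_peaks if p.is_enhancer]

    def regulated(self, factor: str, min_fold: float = 1.5) -> set[str]:
        table = self.log2fc_gata1 if factor == "GATA1" else self.log2fc_gata2
        return {g for g, v in table.items() if 2 ** abs(v) >= min_fold}


def default_config(seed: int = 0, noise_sd: float = 0.5) -> SyntheticConfig:
    """Default study-condition scenario.

    Eight SLC genes carry accessible WGATAR intronic enhancers and are
    co-regulated (all GATA2-activated; GATA1 represses four and activates
    four, mirroring the mixed directionality of the co-regulated cohort).
    Nine further SLC genes are GATA2-occupied in closed chromatin and also
    co-regulated, three SLC genes are regulated by a single factor, and
    the remaining genes are nulls/decoys.
    """
    cfg = SyntheticConfig(seed=seed, noise_sd=noise_sd)
    rng = np.random.default_rng([seed, 7])
    g1: dict[str, float] = {}
    g2: dict[str, float] = {}
    hosts = cfg.enhancer_host_ids
    for i, g in enumerate(hosts):
        g2[g] = round(float(rng.uniform(1.0, 3.0)), 3)
        sign = -1.0 if i < len(hosts) // 2 else 1.0
        g1[g] = round(sign * float(rng.uniform(1.0, 3.0)), 3)
    for g in cfg.occupied_only_ids:
        g2[g] = round(float(rng.uniform(1.0, 3.0)), 3)
        g1[g] = round(float(rng.choice([-1.0, 1.0]) * rng.uniform(1.0, 3.0)), 3)
    # singly regulated SLCs beyond the occupied set
    rest = cfg.slc_ids[cfg.n_planted_enhancers + cfg.n_occupied_only :]
    for j, g in enumerate(rest[:3]):
        table = g1 if j % 2 == 0 else g2
        table[g] = round(float(rng.choice([-1.0, 1.0]) * rng.uniform(1.0, 2.5)), 3)
    cfg.planted_log2fc_gata1 = g1
    cfg.planted_log2fc_gata2 = g2
    return cfg


# ---------------------------------------------------------------------------
# Genome


def _random_sequence(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, size=n)].tobytes().decode()


def _build_gene(rng: np.random.Generator, gene_id: str, chrom: str,
                tx_start: int, family: str | None) -> GeneModel:
    n_exons = int(rng.integers(MIN_EXONS, MAX_EXONS + 1))
    pos = tx_start
    exons = []
    for i in range(n_exons):
        if i:
            pos += int(rng.integers(INTRON_LEN[0], INTRON_LEN[1] + 1))
        e_len = int(rng.integers(EXON_LEN[0], EXON_LEN[1] + 1))
        exons.append((pos, pos + e_len))
        pos += e_len
    strand = str(rng.choice(["+", "-"]))
    return GeneModel(gene_id, chrom, strand, exons[0][0], exons[-1][1],
                     tuple(exons), family=family)


def _plant_motif(seq_arr: np.ndarray, start: int, instance: str) -> None:
    seq_arr[start : start + len(instance)] = np.frombuffer(
        instance.encode(), dtype="S1"
    )


def generate_genome(
    config: SyntheticConfig,
) -> tuple[dict[str, str], list[GeneModel], GroundTruth]:
    """Deterministically generate sequences, gene models and planted truth."""
    rng = np.random.default_rng([config.seed, 11])
    genes_per_chrom = -(-config.n_genes // config.n_chromosomes)
    slot = config.chrom_length // genes_per_chrom
    if slot < MIN_SLOT:
        raise ValueError(
            f"genome too small to place genes without overlap: slot {slot} bp "
            f"< required {MIN_SLOT} bp (raise chrom_length or lower n_genes)"
        )

    seq_arrays: dict[str, np.ndarray] = {}
    for c in range(config.n_chromosomes):
        seq_arrays[f"chr{c + 1}"] = _BASES[
            rng.integers(0, 4, size=config.chrom_length)
        ].copy()

    slc = set(config.slc_ids)
    genes: list[GeneModel] = []
    for i, gid in enumerate(config.gene_ids):
        chrom = f"chr{i // genes_per_chrom + 1}"
        tx_start = (i % genes_per_chrom) * slot + GENE_OFFSET
        genes.append(_build_gene(rng, gid, chrom, tx_start,
                                 family="SLC" if gid in slc else None))
    by_id = {g.gene_id: g for g in genes}

    planted: list[PlantedPeak] = []
    for gid in config.enhancer_host_ids + config.occupied_only_ids:
        is_host = gid in config.enhancer_host_ids
        g = by_id[gid]
        ranked = g.introns_by_rank()
        rank, istart, iend = ranked[int(rng.integers(len(ranked)))]
        width = int(rng.integers(config.peak_width[0], config.peak_width[1] + 1))
        width = min(width, iend - istart)
        start = istart + int(rng.integers(iend - istart - width + 1))
        motifs: tuple[str, ...] = ()
        if is_host:
            arr = seq_arrays[g.chrom]
            w = "AT"[int(rng.integers(2))]
            r = "AG"[int(rng.integers(2))]
            m_off = start + int(rng.integers(width - 6 + 1))
            _plant_motif(arr, m_off, f"{w}GATA{r}")
            motifs = ("WGATAR",)
            if config.plant_ebox and width >= 20:
                # place the E-box clear of the GATA site
                for _ in range(50):
                    e_off = start + int(rng.integers(width - 6 + 1))
                    if abs(e_off - m_off) >= 6:
                        _plant_motif(arr, e_off, "CAGCTG")
                        motifs = ("WGATAR", "Ebox")
                        break
        planted.append(
            PlantedPeak(gid, g.chrom, start, start + width, rank, motifs,
                        accessible=is_host, gata1_occupied=True, ccre=is_host)
        )

    truth = GroundTruth(
        log2fc_gata1=dict(config.planted_log2fc_gata1),
        log2fc_gata2=dict(config.planted_log2fc_gata2),
        planted_peaks=planted,
    )
    sequences = {c: a.tobytes().decode() for c, a in seq_arrays.items()}
    return sequences, genes, truth


# ---------------------------------------------------------------------------
# Expression


def generate_expression(
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    config: SyntheticConfig,
) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Two replicate contrasts with planted effects and log2-normal noise."""
    if config.n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    rng = np.random.default_rng([config.seed, 22])
    gene_ids = [g.gene_id for g in genes]
    n = len(gene_ids)
    baseline = rng.normal(config.baseline_log2_mean, config.baseline_log2_sd, size=n)
    # emulated genes are expressed in the system: floor baselines at 2 TPM
    # so fold estimates are not dominated by the pseudocount
    baseline = np.maximum(baseline, 1.0)

    def contrast(action_lfc: Mapping[str, float], sign: float,
                 group_a: str, group_b: str) -> ExpressionMatrix:
        lfc = np.array([sign * action_lfc.get(g, 0.0) for g in gene_ids])
        cols, data = [], []
        for grp, shift in ((group_a, 0.0), (group_b, 1.0)):
            for r in range(config.n_replicates):
                noise = (rng.normal(0.0, config.noise_sd, size=n)
                         if config.noise_sd > 0 else np.zeros(n))
                data.append(2.0 ** (baseline + shift * lfc + noise))
                cols.append(f"{grp}_{r + 1}")
        df = pd.DataFrame(np.column_stack(data), index=gene_ids, columns=cols)
        conditions = {c: c.rsplit("_", 1)[0] for c in cols}
        return ExpressionMatrix(df, conditions)

    # GATA1 system: activation appears as an increase upon induction
    expr_g1 = contrast(truth.log2fc_gata1, +1.0, "untreated", "estradiol")
    # GATA2 system: activation appears as a decrease in the enhancer mutant
    expr_g2 = contrast(truth.log2fc_gata2, -1.0, "wt", "mut")
    return expr_g1, expr_g2


# ---------------------------------------------------------------------------
# Peaks


def _intergenic_zones(genes: Sequence[GeneModel], chrom: str, chrom_length: int,
                      min_len: int) -> list[tuple[int, int]]:
    spans = sorted((g.tx_start, g.tx_end) for g in genes if g.chrom == chrom)
    zones = []
    prev = 0
    for s, e in spans + [(chrom_length, chrom_length)]:
        lo, hi = prev + DECOY_CLEARANCE, s - DECOY_CLEARANCE
        if hi - lo >= min_len:
            zones.append((lo, hi))
        prev = max(prev, e)
    return zones


def generate_peaks(
    genes: Sequence[GeneModel],
    truth: GroundTruth,
    config: SyntheticConfig,
) -> tuple[list[GenomicInterval], list[GenomicInterval],
           list[GenomicInterval], list[GenomicInterval]]:
    """GATA1 ChIP, GATA2 ChIP, ATAC and cCRE interval sets.

    Every planted peak is covered by a GATA2 peak; GATA1/ATAC/cCRE follow
    the truth flags. Decoy peaks are placed in intergenic space with a
    clearance wider than the default peak-to-gene assignment window, so
    decoy genes acquire no assignments.
    """
    rng = np.random.default_rng([config.seed, 33])
    gata1, gata2, atac, ccres = [], [], [], []
    for p in truth.planted_peaks:
        gata2.append(GenomicInterval(p.chrom, p.start, p.end,
                                     name=f"{p.gene_id}.g2"))
        if p.gata1_occupied:
            gata1.append(GenomicInterval(p.chrom, p.start, p.end,
                                         name=f"{p.gene_id}.g1"))
        if p.accessible:
            atac.append(GenomicInterval(p.chrom, max(0, p.start - 50),
                                        p.end + 50, name=f"{p.gene_id}.atac"))
        if p.ccre:
            mid = (p.start + p.end) // 2
            half = min(75, (p.end - p.start) // 2)
            ccres.append(GenomicInterval(p.chrom, mid - half, mid + half,
                                         name=f"{p.gene_id}.ccre"))

    max_w = config.peak_width[1]
    zones_by_chrom = {
        f"chr{c + 1}": _intergenic_zones(genes, f"chr{c + 1}",
                                         config.chrom_length, max_w + 10)
        for c in range(config.n_chromosomes)
    }
    all_zones = [(c, lo, hi) for c, zs in zones_by_chrom.items() for lo, hi in zs]
    for assay, out in (("g1", gata1), ("g2", gata2), ("atac", atac), ("ccre", ccres)):
        for d in range(config.n_decoy_peaks):
            c, lo, hi = all_zones[int(rng.integers(len(all_zones)))]
            w = int(rng.integers(config.peak_width[0], max_w + 1))
            s = lo + int(rng.integers(hi - lo - w + 1))
            out.append(GenomicInterval(c, s, s + w, name=f"decoy.{assay}.{d}"))
    key = lambda iv: (iv.chrom, iv.start, iv.end)
    return sorted(gata1, key=key), sorted(gata2, key=key), \
        sorted(atac, key=key), sorted(ccres, key=key)


# ---------------------------------------------------------------------------
# Registry + output bundle


def make_registry(genes: Sequence[GeneModel], truth: GroundTruth,
                  config: SyntheticConfig) -> pd.DataFrame:
    """Transporter registry covering genome SLC genes, padded with
    registry-only entries to the configured ensemble size."""
    rng = np.random.default_rng([config.seed, 44])
    classes = ["amino acid", "metal", "nucleoside/nucleotide", "vitamin", "other"]
    class_p = [0.22, 0.18, 0.16, 0.08, 0.36]
    locs = ["plasma membrane", "mitochondria", "ER/Golgi", "lysosome", "unknown"]
    loc_p = [0.5, 0.15, 0.15, 0.05, 0.15]

    planted_ids = {p.gene_id for p in truth.planted_peaks}
    host_ids = {p.gene_id for p in truth.planted_peaks if p.is_enhancer}
    rows = []
    slc_genes = [g for g in genes if g.family == "SLC"]
    for i, g in enumerate(slc_genes):
        # phenotype annotations avoid non-host planted genes so that planted
        # enhancer hosts dominate the evidence score deterministically
        if g.gene_id in host_ids:
            phenotype = i % 4 == 0
        elif g.gene_id in planted_ids:
            phenotype = False
        else:
            phenotype = bool(rng.random() < 0.1)
        rows.append({
            "gene_id": g.gene_id,
            "family": f"Slc{i + 1}",
            "substrate_class": str(rng.choice(classes, p=class_p)),
            "localization": str(rng.choice(locs, p=loc_p)),
            "phenotype": phenotype,
        })
    for j in range(config.ensemble_size - len(rows)):
        rows.append({
            "gene_id": f"ens{j:04d}",
            "family": f"Slc{len(slc_genes) + j + 1}",
            "substrate_class": str(rng.choice(classes, p=class_p)),
            "localization": str(rng.choice(locs, p=loc_p)),
            "phenotype": bool(rng.random() < 0.05),
        })
    df = pd.DataFrame(rows)
    return df.set_index("gene_id", drop=False)


def truth_tables(truth: GroundTruth,
                 config: SyntheticConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    gene_rows = []
    for gid in config.gene_ids:
        gene_rows.append({
            "gene_id": gid,
            "log2fc_gata1": truth.log2fc_gata1.get(gid, 0.0),
            "log2fc_gata2": truth.log2fc_gata2.get(gid, 0.0),
            "direction_gata1": truth.direction("GATA1", gid) or "none",
            "direction_gata2": truth.direction("GATA2", gid) or "none",
        })
    peak_rows = [dataclasses.asdict(p) | {"is_enhancer": p.is_enhancer,
                                          "motifs": ",".join(p.motifs) or "."}
                 for p in truth.planted_peaks]
    return pd.DataFrame(gene_rows), pd.DataFrame(peak_rows)


def write_all(config: SyntheticConfig, outdir: str | Path) -> dict[str, Path]:
    """Generate and write the full synthetic input bundle; returns paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sequences, genes, truth = generate_genome(config)
    expr_g1, expr_g2 = generate_expression(genes, truth, config)
    gata1, gata2, atac, ccres = generate_peaks(genes, truth, config)
    registry = make_registry(genes, truth, config)
    gene_truth, peak_truth = truth_tables(truth, config)

    paths = {k: outdir / v for k, v in {
        "genome": "genome.fa", "genes": "genes.gff3",
        "gata1_peaks": "gata1_chip.bed", "gata2_peaks": "gata2_chip.bed",
        "atac_peaks": "atac.bed", "ccres": "ccres.bed",
        "expr_gata1": "expr_gata1.tsv", "expr_gata2": "expr_gata2.tsv",
        "registry": "registry.tsv",
        "truth_genes": "truth_genes.tsv", "truth_peaks": "truth_peaks.tsv",
    }.items()}
    write_fasta(sequences, paths["genome"])
    write_gff3(genes, paths["genes"])
    write_bed(gata1, paths["gata1_peaks"])
    write_bed(gata2, paths["gata2_peaks"])
    write_bed(atac, paths["atac_peaks"])
    write_bed(ccres, paths["ccres"])
    write_expression_table(expr_g1, paths["expr_gata1"])
    write_expression_table(expr_g2, paths["expr_gata2"])
    registry.to_csv(paths["registry"], sep="\t", index=False)
    gene_truth.to_csv(paths["truth_genes"], sep="\t", index=False)
    peak_truth.to_csv(paths["truth_peaks"], sep="\t", index=False)
    return paths
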