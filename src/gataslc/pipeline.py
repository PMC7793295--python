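"""End-to-end pipeline: simulate -> DE -> partition -> integrate -> motif
test -> prioritize, under one config with one global seed.

The global seed is expanded into independent per-stage streams by seeding
``numpy.random.default_rng`` with ``[seed, stage_tag]``, so a stage rerun
in isolation reproduces its in-pipeline output exactly. Every run rewrites
all outputs from scratch; the summary table is fully deterministic given
the config.
"""

from __future__ import annotations

import dataclasses
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import annotate, cohorts, diffexp, motifs, prioritize, simulate
from .diffexp import calls_to_frame
from .formats import REGISTRY_CLASSES, write_bed

__all__ = ["PipelineConfig", "run_all"]

STAGE_TAGS = {"simulate": 0, "de": 1, "partition": 2, "integrate": 3,
              "motif_test": 4, "prioritize": 5}


@dataclass
class PipelineConfig:
    """All pipeline constants, config-file round-trippable."""

    seed: int = 0
    fold_threshold: float = 1.5
    fdr_threshold: float = 0.05
    pseudocount: float = 0.5
    window: int = 10_000
    n_iter: int = 10_000
    alpha: float = 0.05
    top_k: int = 10
    motif_set: tuple[str, ...] = ("wgatar", "ebox")
    statistic: str = "presence"
    ensemble_size: int = 456
    noise_sd: float = 0.5
    score_weights: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.fold_threshold < 1:
            raise ValueError("fold_threshold must be >= 1")
        if not 0 <= self.fdr_threshold <= 1 or not 0 <= self.alpha <= 1:
            raise ValueError("fdr_threshold and alpha must lie in [0, 1]")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be positive")
        if self.window < 0 or self.n_iter < 1 or self.top_k < 1:
            raise ValueError("window, n_iter and top_k must be positive")
        unknown = set(self.motif_set) - {"wgatar", "ebox"}
        if unknown:
            raise ValueError(f"unknown motifs {sorted(unknown)}")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["motif_set"] = list(self.motif_set)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if "motif_set" in d:
            d["motif_set"] = tuple(d["motif_set"])
        return cls(**d)


MOTIF_BY_NAME = {"wgatar": motifs.WGATAR, "ebox": motifs.EBOX}


def _log(msg: str, log_lines: list[str]) -> None:
    log_lines.append(msg)
    print(msg, file=sys.stderr)


def run_all(
    config: PipelineConfig,
    outdir: str | Path,
    synth_config: simulate.SyntheticConfig | None = None,
) -> dict[str, Any]:
    """Run every stage on a synthetic dataset and write a report bundle.

    Returns the in-memory results keyed by stage. Writes per-stage TSV/BED
    outputs plus ``summary.tsv`` and ``run.log`` under ``outdir``.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    _log(f"config: {dataclasses.asdict(config)}", log)

    # -- stage: simulate -------------------------------------------------
    if synth_config is None:
        synth_config = simulate.default_config(
            seed=config.seed, noise_sd=config.noise_sd
        )
    _log(f"simulate: seed={synth_config.seed} n_genes={synth_config.n_genes} "
         f"noise_sd={synth_config.noise_sd}", log)
    sequences, genes, truth = simulate.generate_genome(synth_config)
    expr_g1, expr_g2 = simulate.generate_expression(genes, truth, synth_config)
    gata1_pk, gata2_pk, atac_pk, ccre_pk = simulate.generate_peaks(
        genes, truth, synth_config
    )
    registry = simulate.make_registry(genes, truth, synth_config)
    simulate.write_all(synth_config, outdir / "inputs")

    # -- stage: de -------------------------------------------------------
    fc_g1 = diffexp.compute_fold_changes(expr_g1, "untreated", "estradiol",
                                         pseudocount=config.pseudocount)
    fc_g2 = diffexp.compute_fold_changes(expr_g2, "wt", "mut",
                                         pseudocount=config.pseudocount)
    family_of = {g.gene_id: g.family for g in genes}
    calls_g1 = diffexp.call_regulated_genes(
        fc_g1, "GATA1", config.fold_threshold, config.fdr_threshold,
        family_filter="SLC", family_of=family_of)
    calls_g2 = diffexp.call_regulated_genes(
        fc_g2, "GATA2", config.fold_threshold, config.fdr_threshold,
        family_filter="SLC", family_of=family_of)
    fc_g1.to_csv(outdir / "fold_changes_gata1.tsv", sep="\t")
    fc_g2.to_csv(outdir / "fold_changes_gata2.tsv", sep="\t")
    calls_to_frame(calls_g1).to_csv(outdir / "calls_gata1.tsv", sep="\t", index=False)
    calls_to_frame(calls_g2).to_csv(outdir / "calls_gata2.tsv", sep="\t", index=False)
    _log(f"de: {len(calls_g1)} GATA1 calls, {len(calls_g2)} GATA2 calls", log)

    # -- stage: partition ------------------------------------------------
    part = cohorts.partition_cohorts(calls_g1, calls_g2)
    part.to_frame().to_csv(outdir / "partition.tsv", sep="\t", index=False)
    enrich_rows = []
    for label in REGISTRY_CLASSES:
        if part.shared and (registry["substrate_class"] == label).any():
            r = cohorts.substrate_enrichment(part.shared, label, registry)
            enrich_rows.append(dataclasses.asdict(r))
    enrich_df = pd.DataFrame(enrich_rows)
    enrich_df.to_csv(outdir / "enrichment.tsv", sep="\t", index=False)
    _log(f"partition: {part.sizes()}", log)

    # -- stage: integrate ------------------------------------------------
    asn = {
        "GATA1": annotate.assign_peaks_to_genes(gata1_pk, genes, config.window),
        "GATA2": annotate.assign_peaks_to_genes(gata2_pk, genes, config.window),
        "ATAC": annotate.assign_peaks_to_genes(atac_pk, genes, config.window),
        "cCRE": annotate.assign_peaks_to_genes(ccre_pk, genes, config.window),
    }
    candidates = annotate.call_intronic_enhancers(
        asn["GATA2"], genes, gata1_pk, atac_pk, ccre_pk, sequences
    )
    predicted = [c for c in candidates if c.is_predicted_enhancer]
    occupancy = annotate.occupancy_summary(sorted(part.union), asn)
    annotate.candidates_to_frame(candidates).to_csv(
        outdir / "enhancer_candidates.tsv", sep="\t", index=False)
    write_bed([c.interval for c in predicted], outdir / "predicted_enhancers.bed")
    occupancy.to_csv(outdir / "occupancy.tsv", sep="\t")
    _log(f"integrate: {len(candidates)} candidates, {len(predicted)} predicted "
         f"enhancers", log)

    # -- stage: motif_test ----------------------------------------------
    perm_rows = []
    perm_results = {}
    if predicted:
        observed = [c.interval for c in predicted]
        motif_tags = {"wgatar": 0, "ebox": 1}
        for name in config.motif_set:
            res = motifs.permutation_test(
                observed, genes, sequences, MOTIF_BY_NAME[name],
                n_iter=config.n_iter,
                seed=np.random.default_rng(
                    [config.seed, STAGE_TAGS["motif_test"], motif_tags[name]]
                ),
                statistic=config.statistic,
            )
            perm_results[name] = res
            perm_rows.append(res.summary_row())
            pd.DataFrame({
                "statistic_value": range(len(res.null_counts)),
                "count": res.null_counts,
            }).to_csv(outdir / f"null_histogram_{name}.tsv", sep="\t", index=False)
    perm_df = pd.DataFrame(perm_rows)
    perm_df.to_csv(outdir / "motif_enrichment.tsv", sep="\t", index=False)
    _log(f"motif_test: {perm_rows}", log)

    # -- stage: prioritize ----------------------------------------------
    records = prioritize.select_candidates(
        part, calls_g1, calls_g2, occupancy, candidates, registry,
        k=config.top_k, weights=config.score_weights or None,
    )
    prioritize.records_to_frame(records).to_csv(
        outdir / "candidates_ranked.tsv", sep="\t", index=False)
    _log(f"prioritize: top {len(records)} of {len(part.shared)} shared genes", log)

    # -- summary ---------------------------------------------------------
    summary_rows = [("seed", config.seed)]
    summary_rows += sorted(part.sizes().items())
    summary_rows.append(("predicted_enhancers", len(predicted)))
    summary_rows.append(("enhancer_genes",
                         len({c.gene_id for c in predicted})))
    for name in sorted(perm_results):
        r = perm_results[name]
        summary_rows.append((f"perm_p_{name}", r.p_empirical))
        summary_rows.append((f"perm_observed_{name}", r.observed_statistic))
    for row in sorted(enrich_rows, key=lambda r: r["class_label"]):
        summary_rows.append((f"enrich_p_{row['class_label']}", row["p_value"]))
    summary_rows.append(
        ("top_genes", ",".join(r.gene_id for r in records)))
    summary = pd.DataFrame(summary_rows, columns=["key", "value"])
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)
    (outdir / "run.log").write_text("\n".join(log) + "\n")

    return {
        "genes": genes, "truth": truth, "sequences": sequences,
        "expr": (expr_g1, expr_g2), "fold_changes": (fc_g1, fc_g2),
        "calls": (calls_g1, calls_g2), "partition": part,
        "enrichment": enrich_df, "assignments": asn,
        "candidates": candidates, "predicted": predicted,
        "occupancy": occupancy, "permutation": perm_results,
        "ranked": records, "summary": summary, "registry": registry,
    }
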