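"""Candidate ranking: fold-change top-k lists and evidence-weighted scoring.

Two rankings are exposed. ``rank_top_k`` is the plain magnitude ranking
(top activated / top repressed genes of one factor). ``select_candidates``
scores the co-regulated cohort with a transparent linear combination of
log2 fold-change magnitude and boolean evidence flags (occupancy,
accessibility, cCRE overlap, predicted intronic enhancer, phenotype
annotation) and returns the top k records with all evidence columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log2
from typing import Mapping, Sequence

import pandas as pd

from .annotate import EnhancerCandidate
from .cohorts import CohortPartition
from .diffexp import RegulationCall

__all__ = [
    "EVIDENCE_FLAGS",
    "DEFAULT_WEIGHTS",
    "PriorityRecord",
    "rank_top_k",
    "priority_score",
    "select_candidates",
]

EVIDENCE_FLAGS = (
    "gata1_occupied",
    "gata2_occupied",
    "accessible",
    "ccre",
    "has_intronic_enhancer",
    "phenotype_annotation",
)
# w_fc scales log2(fold magnitude); evidence flags count 1 each, phenotype 2
DEFAULT_WEIGHTS = {"fc": 1.0, **{f: 1.0 for f in EVIDENCE_FLAGS},
                   "phenotype_annotation": 2.0}


@dataclass(frozen=True)
class PriorityRecord:
    gene_id: str
    fold_change: float  # magnitude, >= 1
    direction_gata1: str
    direction_gata2: str
    flags: tuple[bool, ...]  # in EVIDENCE_FLAGS order
    score: float
    rank: int

    def flag(self, name: str) -> bool:
        return self.flags[EVIDENCE_FLAGS.index(name)]


def rank_top_k(
    calls: Sequence[RegulationCall],
    direction: str,
    k: int,
) -> list[str]:
    """Top-k gene ids of one direction by fold-change magnitude.

    Ties are broken alphabetically by gene id; k beyond the cohort size
    returns every gene of that direction.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    picked = [c for c in calls if c.direction == direction]
    picked.sort(key=lambda c: (-c.fold_change, c.gene_id))
    return [c.gene_id for c in picked[:k]]


def priority_score(
    fold_change: float,
    flags: Mapping[str, bool],
    weights: Mapping[str, float] | None = None,
) -> float:
    """score = w_fc * log2(fold magnitude) + sum of weighted evidence flags."""
    w = dict(DEFAULT_WEIGHTS)
    if weights:
        w.update(weights)
    if any(v < 0 for v in w.values()):
        raise ValueError("weights must be nonnegative")
    if fold_change < 1:
        raise ValueError("fold_change is a magnitude and must be >= 1")
    score = w["fc"] * log2(fold_change)
    for name in EVIDENCE_FLAGS:
        if flags.get(name, False):
            score += w[name]
    return score


def select_candidates(
    partition: CohortPartition,
    calls_g1: Sequence[RegulationCall],
    calls_g2: Sequence[RegulationCall],
    occupancy: pd.DataFrame,
    enhancers: Sequence[EnhancerCandidate],
    registry: pd.DataFrame | None = None,
    k: int = 10,
    weights: Mapping[str, float] | None = None,
) -> list[PriorityRecord]:
    """Score and rank the co-regulated cohort; emit the top k records.

    ``occupancy`` is the boolean gene x assay table from
    :func:`gataslc.annotate.occupancy_summary` (columns GATA1/GATA2/
    ATAC/cCRE, any subset). The fold-change magnitude of a shared gene is
    the larger of its two per-factor magnitudes. Ordering is score
    descending, then fold magnitude, then gene id.
    """
    if not partition.shared:
        import warnings

        warnings.warn("shared cohort is empty; no candidates to rank",
                      stacklevel=2)
        return []
    by_g1 = {c.gene_id: c for c in calls_g1}
    by_g2 = {c.gene_id: c for c in calls_g2}
    enhancer_genes = {e.gene_id for e in enhancers if e.is_predicted_enhancer}
    phenotype = (
        registry["phenotype"].to_dict() if registry is not None
        and "phenotype" in registry.columns else {}
    )

    records = []
    for gene in sorted(partition.shared):
        c1, c2 = by_g1[gene], by_g2[gene]
        fold = max(c1.fold_change, c2.fold_change)

        def occ(col: str) -> bool:
            return bool(occupancy.at[gene, col]) if (
                col in getattr(occupancy, "columns", ()) and gene in occupancy.index
            ) else False

        flags = {
            "gata1_occupied": occ("GATA1"),
            "gata2_occupied": occ("GATA2"),
            "accessible": occ("ATAC"),
            "ccre": occ("cCRE"),
            "has_intronic_enhancer": gene in enhancer_genes,
            "phenotype_annotation": bool(phenotype.get(gene, False)),
        }
        records.append(
            (
                gene,
                fold,
                c1.direction,
                c2.direction,
                tuple(flags[f] for f in EVIDENCE_FLAGS),
                priority_score(fold, flags, weights),
            )
        )
    records.sort(key=lambda r: (-r[5], -r[1], r[0]))
    return [
        PriorityRecord(gene_id=g, fold_change=f, direction_gata1=d1,
                       direction_gata2=d2, flags=fl, score=s, rank=i + 1)
        for i, (g, f, d1, d2, fl, s) in enumerate(records[:k])
    ]


def records_to_frame(records: Sequence[PriorityRecord]) -> pd.DataFrame:
    rows = []
    for r in records:
        row = {
            "rank": r.rank,
            "gene_id": r.gene_id,
            "fold_change": r.fold_change,
            "direction_gata1": r.direction_gata1,
            "direction_gata2": r.direction_gata2,
            "score": r.score,
        }
        row.update({name: r.flags[i] for i, name in enumerate(EVIDENCE_FLAGS)})
        rows.append(row)
    return pd.DataFrame(
        rows,
        columns=["rank", "gene_id", "fold_change", "direction_gata1",
                 "direction_gata2", "score", *EVIDENCE_FLAGS],
    )
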