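"""Venn partition of regulated-gene cohorts and substrate-class enrichment.

The co-regulated (shared) cohort is further split into four direction
groups keyed (GATA2 direction, GATA1 direction) with "up" = activated by
the factor — e.g. a gene activated by GATA2 and repressed by GATA1 falls
in the ("up", "down") group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
from scipy import stats

from .diffexp import RegulationCall
from .formats import REGISTRY_CLASSES

__all__ = [
    "CohortPartition",
    "EnrichmentResult",
    "partition_cohorts",
    "direction_group_of",
    "substrate_enrichment",
]

DIRECTION_KEYS = (("up", "up"), ("up", "down"), ("down", "up"), ("down", "down"))


def _index_calls(calls: Iterable[RegulationCall], factor: str) -> dict[str, RegulationCall]:
    out: dict[str, RegulationCall] = {}
    for c in calls:
        prev = out.get(c.gene_id)
        if prev is not None and (prev.direction != c.direction):
            raise ValueError(
                f"conflicting {factor} calls for {c.gene_id}: "
                f"{prev.direction} vs {c.direction}"
            )
        out[c.gene_id] = c
    return out


@dataclass
class CohortPartition:
    g1_only: set[str]
    g2_only: set[str]
    shared: set[str]
    direction_groups: dict[tuple[str, str], set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.g1_only & self.g2_only or self.g1_only & self.shared \
                or self.g2_only & self.shared:
            raise ValueError("Venn sets must be pairwise disjoint")
        grouped = set().union(*self.direction_groups.values()) if self.direction_groups else set()
        if self.direction_groups and grouped != self.shared:
            raise ValueError("direction groups must partition the shared set")

    @property
    def union(self) -> set[str]:
        return self.g1_only | self.g2_only | self.shared

    def sizes(self) -> dict[str, int]:
        out = {
            "g1_only": len(self.g1_only),
            "g2_only": len(self.g2_only),
            "shared": len(self.shared),
            "g1_total": len(self.g1_only) + len(self.shared),
            "g2_total": len(self.g2_only) + len(self.shared),
        }
        for key in DIRECTION_KEYS:
            out[f"g2_{key[0]}/g1_{key[1]}"] = len(self.direction_groups.get(key, set()))
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = []
        group_of = {g: k for k, gs in self.direction_groups.items() for g in gs}
        for name, genes in (("g1_only", self.g1_only), ("g2_only", self.g2_only),
                            ("shared", self.shared)):
            for g in sorted(genes):
                k = group_of.get(g)
                rows.append({"gene_id": g, "venn_set": name,
                             "direction_group": f"{k[0]}/{k[1]}" if k else "."})
        return pd.DataFrame(rows, columns=["gene_id", "venn_set", "direction_group"])


def partition_cohorts(
    calls_g1: Sequence[RegulationCall],
    calls_g2: Sequence[RegulationCall],
) -> CohortPartition:
    """Exact set algebra on gene ids, plus four-way direction grouping."""
    by_g1 = _index_calls(calls_g1, "GATA1")
    by_g2 = _index_calls(calls_g2, "GATA2")
    g1, g2 = set(by_g1), set(by_g2)
    shared = g1 & g2
    groups: dict[tuple[str, str], set[str]] = {k: set() for k in DIRECTION_KEYS}
    for gene in shared:
        d2 = "up" if by_g2[gene].direction == "activated" else "down"
        d1 = "up" if by_g1[gene].direction == "activated" else "down"
        groups[(d2, d1)].add(gene)
    return CohortPartition(g1 - g2, g2 - g1, shared, groups)


def direction_group_of(
    gene_id: str,
    calls_g1: Sequence[RegulationCall],
    calls_g2: Sequence[RegulationCall],
) -> tuple[str, str]:
    """(GATA2 direction, GATA1 direction) for a co-regulated gene."""
    by_g1 = _index_calls(calls_g1, "GATA1")
    by_g2 = _index_calls(calls_g2, "GATA2")
    if gene_id not in by_g1 or gene_id not in by_g2:
        raise ValueError(f"{gene_id} is not in both cohorts")
    return (
        "up" if by_g2[gene_id].direction == "activated" else "down",
        "up" if by_g1[gene_id].direction == "activated" else "down",
    )


@dataclass(frozen=True)
class EnrichmentResult:
    class_label: str
    count_in_cohort: int
    cohort_size: int
    count_in_ensemble: int
    ensemble_size: int
    chi2_statistic: float
    p_value: float
    method: str  # "chi2" or "fisher"


def substrate_enrichment(
    cohort: set[str],
    class_label: str,
    registry: pd.DataFrame,
    min_expected: float = 5.0,
) -> EnrichmentResult:
    """2x2 {in/out cohort} x {in/out class} test against the full ensemble.

    Pearson chi-square (1 df, no continuity correction); Fisher's exact
    test is substituted when any expected cell drops below ``min_expected``
    and reported as such in ``method``.
    """
    if not cohort:
        raise ValueError("empty cohort")
    if class_label not in REGISTRY_CLASSES:
        raise ValueError(f"unknown substrate class {class_label!r}")
    missing = cohort - set(registry.index)
    if missing:
        raise ValueError(f"cohort genes absent from registry: {sorted(missing)[:5]}")
    in_class = set(registry.index[registry["substrate_class"] == class_label])
    if not in_class:
        raise ValueError(f"class {class_label!r} has no members in the registry")

    n = len(registry)
    a = len(cohort & in_class)               # cohort, class
    b = len(cohort) - a                      # cohort, other class
    c = len(in_class) - a                    # rest of ensemble, class
    d = n - len(cohort) - c                  # rest, other
    table = [[a, b], [c, d]]

    expected_min = min(
        (a + b) * (a + c) / n, (a + b) * (b + d) / n,
        (c + d) * (a + c) / n, (c + d) * (b + d) / n,
    )
    res = stats.chi2_contingency(table, correction=False)
    chi2 = float(res.statistic)
    if expected_min < min_expected:
        # statistic still reported; p-value switches to the exact test
        p, method = float(stats.fisher_exact(table).pvalue), "fisher"
    else:
        p, method = float(res.pvalue), "chi2"
    return EnrichmentResult(
        class_label=class_label,
        count_in_cohort=a,
        cohort_size=len(cohort),
        count_in_ensemble=len(in_class),
        ensemble_size=n,
        chi2_statistic=chi2,
        p_value=p,
        method=method,
    )
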