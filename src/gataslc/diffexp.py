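"""Per-gene fold changes, significance and regulated-gene calling.

A gene is called regulated by a factor when its fold-change magnitude
``max(FC, 1/FC)`` reaches the fold threshold (1.5 by default, inclusive)
and the BH-adjusted p-value passes the FDR threshold. Significance uses an
unpaired two-tailed Student's t test on log2(TPM + pseudocount); Welch's
unequal-variance variant is available via ``equal_var=False``.

Direction is reported as the factor's action, not the raw contrast sign:
in the GATA1 induction system "activated" means up upon induction, while
in the GATA2 enhancer-mutant system "activated" means *down* in the mutant
relative to wild type (the factor normally sustains the gene).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .formats import ExpressionMatrix

__all__ = [
    "RegulationCall",
    "compute_fold_changes",
    "call_regulated_genes",
    "DEFAULT_ORIENTATION",
]

# which raw contrast sign counts as the factor activating the gene
DEFAULT_ORIENTATION = {"GATA1": "up", "GATA2": "down"}


@dataclass(frozen=True)
class RegulationCall:
    gene_id: str
    factor: str
    direction: str        # "activated" | "repressed"
    fold_change: float    # magnitude, >= 1
    fdr: float

    def __post_init__(self) -> None:
        if self.direction not in ("activated", "repressed"):
            raise ValueError(f"bad direction {self.direction!r}")
        if self.fold_change < 1:
            raise ValueError("fold_change is a magnitude and must be >= 1")


def compute_fold_changes(
    expr: ExpressionMatrix,
    group_a: str,
    group_b: str,
    pseudocount: float = 0.5,
    equal_var: bool = True,
    drop_unexpressed: bool = True,
) -> pd.DataFrame:
    """Fold changes (b vs a) with t-test p-values and BH FDR.

    Returns a DataFrame indexed by gene id with columns ``mean_a``,
    ``mean_b``, ``log2fc``, ``p_value``, ``fdr``, ``tested``. Genes whose
    means are below the pseudocount in both conditions are dropped before
    the FDR pass (not expressed in the system). With fewer than two
    replicates in either group p is set to 1 and ``tested`` is False.

    Zero-variance convention: when both groups are exactly constant the
    t statistic is undefined; p is 1 if the means agree and 0 otherwise
    (perfect separation).
    """
    a = expr.group_values(group_a).to_numpy(dtype=float)
    b = expr.group_values(group_b).to_numpy(dtype=float)
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2((mean_b + pseudocount) / (mean_a + pseudocount))

    la, lb = np.log2(a + pseudocount), np.log2(b + pseudocount)
    tested = a.shape[1] >= 2 and b.shape[1] >= 2
    if tested:
        import warnings

        with np.errstate(divide="ignore", invalid="ignore"), \
                warnings.catch_warnings():
            # constant replicate vectors are legal input; the resulting NaNs
            # are resolved by the zero-variance convention below
            warnings.simplefilter("ignore", RuntimeWarning)
            p = stats.ttest_ind(lb, la, axis=1, equal_var=equal_var).pvalue
        degenerate = np.isnan(p)
        if degenerate.any():
            equal_means = np.isclose(la.mean(axis=1), lb.mean(axis=1))
            p = np.where(degenerate, np.where(equal_means, 1.0, 0.0), p)
    else:
        p = np.ones_like(log2fc)

    df = pd.DataFrame(
        {
            "mean_a": mean_a,
            "mean_b": mean_b,
            "log2fc": log2fc,
            "p_value": p,
            "tested": tested,
        },
        index=pd.Index(expr.gene_ids, name="gene_id"),
    )
    if drop_unexpressed:
        df = df[(df["mean_a"] >= pseudocount) | (df["mean_b"] >= pseudocount)]
    df = df.copy()
    if len(df):
        df["fdr"] = multipletests(df["p_value"].to_numpy(), method="fdr_bh")[1]
    else:
        df["fdr"] = pd.Series(dtype=float)
    return df


def call_regulated_genes(
    records: pd.DataFrame,
    factor: str,
    fold_threshold: float = 1.5,
    fdr_threshold: float = 0.05,
    activated_when: str | None = None,
    family_filter: str | None = None,
    family_of: Mapping[str, str | None] | None = None,
) -> list[RegulationCall]:
    """Apply the >=1.5-fold + FDR criterion and orient directions.

    ``activated_when`` is "up" or "down": the raw contrast sign that means
    the factor activates the gene (defaults per factor, see module notes).
    ``family_filter`` keeps only genes whose ``family_of`` entry matches.
    """
    if fold_threshold < 1:
        raise ValueError("fold_threshold must be >= 1")
    if activated_when is None:
        activated_when = DEFAULT_ORIENTATION.get(factor, "up")
    if activated_when not in ("up", "down"):
        raise ValueError("activated_when must be 'up' or 'down'")
    if family_filter is not None and family_of is None:
        raise ValueError("family_filter requires a family_of mapping")

    calls: list[RegulationCall] = []
    for gene_id, row in records.iterrows():
        magnitude = float(2.0 ** abs(row["log2fc"]))
        if magnitude < fold_threshold or row["fdr"] > fdr_threshold:
            continue
        if row["log2fc"] == 0.0:
            continue  # magnitude threshold >= 1 admits this only at threshold 1
        if family_filter is not None and family_of.get(gene_id) != family_filter:
            continue
        raw_up = row["log2fc"] > 0
        activated = raw_up if activated_when == "up" else not raw_up
        calls.append(
            RegulationCall(
                gene_id=str(gene_id),
                factor=factor,
                direction="activated" if activated else "repressed",
                fold_change=magnitude,
                fdr=float(row["fdr"]),
            )
        )
    return sorted(calls, key=lambda c: c.gene_id)


def calls_to_frame(calls: Sequence[RegulationCall]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "gene_id": c.gene_id,
                "factor": c.factor,
                "direction": c.direction,
                "fold_change": c.fold_change,
                "fdr": c.fdr,
            }
            for c in calls
        ],
        columns=["gene_id", "factor", "direction", "fold_change", "fdr"],
    )
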