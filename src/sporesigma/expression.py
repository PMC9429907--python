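"""Differential-expression post-processing and sporulation-gene enrichment.

Consumes per-gene differential-expression tables (log2 fold change and
adjusted p-value from an upstream DE model) with a sporulation-category
annotation.  A gene is called differentially expressed when p < 0.05 and
|fold change| > 2 (i.e. |log2fc| > 1); enrichment of sporulation genes in
the up-regulated set is an exact upper-tail hypergeometric test over the
universe of genes present in the strain's table; transcriptional profiles
of two induction strains are compared by Spearman correlation of log2 fold
changes over shared genes.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import adjust_pvalues  # noqa: F401  (re-exported)

__all__ = [
    "EnrichmentResult",
    "call_degs",
    "hypergeom_enrichment",
    "adjust_pvalues",
    "profile_correlation",
]

DE_COLUMNS = ["gene_id", "log2fc", "p_adj"]


@dataclass(frozen=True)
class EnrichmentResult:
    """Exact hypergeometric upper-tail enrichment of annotated genes.

    Drawing ``n`` genes (the DEG set) from a universe of ``N`` containing
    ``K`` annotated genes, the p-value is P(X >= k) for the observed
    overlap ``k``.
    """

    N: int
    K: int
    n: int
    k: int
    p: float


def call_degs(
    table: pd.DataFrame,
    alpha: float = 0.05,
    fold_change_min: float = 2.0,
    use_raw_p: bool = False,
) -> pd.DataFrame:
    """Call up/down/unchanged genes at p < alpha and |fold change| > min.

    ``table`` needs gene_id, log2fc and p_adj (or p if ``use_raw_p``).
    Genes with missing values are left unchanged with a warning.  Returns
    the table with a ``status`` column; counts via ``status.value_counts``.
    """
    if not (0 < alpha < 1):
        raise ValueError("alpha must lie in (0, 1)")
    if fold_change_min <= 1:
        raise ValueError("fold_change_min must exceed 1")
    pcol = "p" if use_raw_p else "p_adj"
    needed = {"gene_id", "log2fc", pcol}
    if not needed <= set(table.columns):
        raise ValueError(f"DE table needs columns {sorted(needed)}")
    if table["gene_id"].duplicated().any():
        raise ValueError("gene ids must be unique")
    out = table.copy()
    lfc_min = np.log2(fold_change_min)
    missing = out["log2fc"].isna() | out[pcol].isna()
    if missing.any():
        import warnings

        warnings.warn(f"{int(missing.sum())} genes missing log2fc/p: counted as unchanged")
    sig = (out[pcol] < alpha) & ~missing
    out["status"] = "unchanged"
    out.loc[sig & (out["log2fc"] > lfc_min), "status"] = "up"
    out.loc[sig & (out["log2fc"] < -lfc_min), "status"] = "down"
    return out


def hypergeom_enrichment(
    deg_set: Iterable[str], annotation: Iterable[str], universe: Iterable[str]
) -> EnrichmentResult:
    """Upper-tail hypergeometric enrichment of annotated genes in a DEG set.

    ``universe`` is all genes of the strain's table; ``annotation`` the
    sporulation-flagged genes.  p = P(X >= k), exact summation (scipy
    survival function); k = 0 gives p = 1.
    """
    U = set(universe)
    if not U:
        raise ValueError("empty universe")
    D = set(deg_set)
    if not D <= U:
        raise ValueError("DEG set must be a subset of the universe")
    A = set(annotation) & U
    N, K, n = len(U), len(A), len(D)
    k = len(D & A)
    p = float(sps.hypergeom.sf(k - 1, N, K, n))
    return EnrichmentResult(N=N, K=K, n=n, k=k, p=min(p, 1.0))


def enrichment_from_table(
    table: pd.DataFrame,
    alpha: float = 0.05,
    fold_change_min: float = 2.0,
    direction: str = "up",
) -> EnrichmentResult:
    """DEG calling + enrichment in one step for a table with is_sporulation."""
    if "is_sporulation" not in table.columns:
        raise ValueError("table needs an is_sporulation column")
    called = call_degs(table, alpha=alpha, fold_change_min=fold_change_min)
    if direction == "both":
        degs = called.loc[called["status"] != "unchanged", "gene_id"]
    else:
        degs = called.loc[called["status"] == direction, "gene_id"]
    annot = table.loc[table["is_sporulation"].astype(bool), "gene_id"]
    return hypergeom_enrichment(degs, annot, table["gene_id"])


def profile_correlation(
    table_a: pd.DataFrame, table_b: pd.DataFrame
) -> tuple[float, int]:
    """Spearman rho of log2 fold changes over genes shared by two strains."""
    a = table_a.set_index("gene_id")["log2fc"]
    b = table_b.set_index("gene_id")["log2fc"]
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared genes")
    rho = sps.spearmanr(a.loc[shared], b.loc[shared])[0]
    return float(rho), len(shared)
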