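"""Cross-model concordance of two differential-expression tables.

Two injury models that perturb the same biology should regulate the same
genes in the same direction.  This module quantifies that: genes
significant (FDR strictly below a threshold) in *both* tables are paired
by symbol, their log2 fold changes are compared by Spearman rank
correlation, and the discordant fraction — the share of paired genes
regulated in opposite directions — is reported.  Genes with an exact-zero
fold change are excluded from the sign comparison (their direction is
undefined).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DegenerateInputError
from .io import DETable


@dataclass
class ConcordanceResult:
    n_genes: int
    spearman_rho: float
    discordant_fraction: float
    gene_table: pd.DataFrame  # gene, log2fc_a, log2fc_b, concordant

    def __post_init__(self) -> None:
        if self.n_genes != len(self.gene_table):
            raise ValueError("n_genes does not match the gene-level table")
        if not -1.0 <= self.spearman_rho <= 1.0:
            raise ValueError("spearman_rho outside [-1, 1]")


def shared_significant(
    table_a: DETable, table_b: DETable, fdr_threshold: float = 0.05
) -> pd.DataFrame:
    """Genes significant (fdr < threshold, strict) in both tables.

    Returns a frame with columns ``gene, log2fc_a, log2fc_b`` ordered
    deterministically by symbol.  An empty intersection yields an empty
    frame (downstream statistics then raise).
    """
    fa = table_a.frame
    fb = table_b.frame
    sa = fa[fa["fdr"] < fdr_threshold][["gene", "log2fc"]]
    sb = fb[fb["fdr"] < fdr_threshold][["gene", "log2fc"]]
    merged = sa.merge(sb, on="gene", suffixes=("_a", "_b"))
    return merged.sort_values("gene", kind="mergesort").reset_index(drop=True)


def spearman_correlation(x, y) -> float:
    """Spearman rank correlation with average ranks for ties."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-d sequences of equal length")
    if x.size < 3:
        raise DegenerateInputError("need at least 3 pairs for a rank correlation")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise DegenerateInputError("constant input; rank correlation undefined")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def discordant_fraction(x, y) -> float:
    """Fraction of pairs with opposite signs, among pairs where both are non-zero."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size == 0:
        raise ValueError("x and y must be non-empty sequences of equal length")
    keep = (x != 0) & (y != 0)
    if not keep.any():
        raise DegenerateInputError("all pairs contain a zero; discordant fraction undefined")
    return float((np.sign(x[keep]) * np.sign(y[keep]) < 0).mean())


def compare_models(
    table_a: DETable, table_b: DETable, fdr_threshold: float = 0.05
) -> ConcordanceResult:
    """Full concordance analysis of two DE tables sharing a gene namespace."""
    pairs = shared_significant(table_a, table_b, fdr_threshold)
    if len(pairs) == 0:
        raise DegenerateInputError("no gene is significant in both tables")
    la = pairs["log2fc_a"].to_numpy()
    lb = pairs["log2fc_b"].to_numpy()
    rho = spearman_correlation(la, lb)
    disc = discordant_fraction(la, lb)
    table = pairs.assign(concordant=np.sign(la) * np.sign(lb) >= 0)
    return ConcordanceResult(
        n_genes=len(table), spearman_rho=rho, discordant_fraction=disc, gene_table=table
    )
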