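"""Exact 2x2 enrichment tests for directional gene-set comparisons.

Two analyses share the same machinery:

* directional curated-annotation enrichment — are differentially expressed
  genes over-represented among genes curated as Protective relative to
  those curated as Detrimental?  Ambiguous genes are excluded entirely and
  the background is restricted to annotated genes detected in the
  experiment;
* predicted miRNA-target enrichment — are predicted targets
  over-represented among upregulated versus downregulated genes after
  miRNA inhibition?

Both reduce to Fisher's exact test on a 2x2 table.  The two-sided p-value
follows the minimum-likelihood rule (sum the point probabilities of every
table with the observed margins whose probability does not exceed the
observed one, within relative tolerance 1e-7) — the convention of R's
``fisher.test``.  Point probabilities are accumulated in log space via
log-gamma so large tables cannot overflow.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .errors import DegenerateInputError, ValidationError
from .io import CuratedAnnotation, TargetGeneSet

#: relative tolerance of the minimum-likelihood inclusion rule
_TWO_SIDED_RELTOL = 1e-7


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Counts (a, b; c, d): a = hits in group 1, b = misses in group 1, etc."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        for name in ("a", "b", "c", "d"):
            v = getattr(self, name)
            if int(v) != v or v < 0:
                raise ValidationError(f"count {name}={v} must be a non-negative integer")
        if self.a + self.b + self.c + self.d == 0:
            raise ValidationError("all-zero contingency table")

    @property
    def odds_ratio(self) -> float:
        """(a*d)/(b*c); division by zero yields inf, 0/0 yields nan."""
        num, den = self.a * self.d, self.b * self.c
        if den == 0:
            return math.nan if num == 0 else math.inf
        return num / den


@dataclass(frozen=True)
class EnrichmentResult:
    table: ContingencyTable2x2
    odds_ratio: float
    pvalue: float
    direction: str = ""

    def __post_init__(self) -> None:
        if not 0.0 < self.pvalue <= 1.0:
            raise ValidationError(f"p-value {self.pvalue} outside (0, 1]")


def _log_pmf_family(table: ContingencyTable2x2) -> tuple[np.ndarray, np.ndarray]:
    """Log point probabilities of every table with the observed margins.

    Returns ``(support, logpmf)`` where ``support`` enumerates the feasible
    values of the (1,1) cell.
    """
    r1, r2 = table.a + table.b, table.c + table.d
    c1 = table.a + table.c
    n = r1 + r2
    lo, hi = max(0, c1 - r2), min(r1, c1)
    support = np.arange(lo, hi + 1)
    # log C(r1, a) + log C(r2, c1-a) - log C(n, c1)
    logpmf = (
        gammaln(r1 + 1)
        - gammaln(support + 1)
        - gammaln(r1 - support + 1)
        + gammaln(r2 + 1)
        - gammaln(c1 - support + 1)
        - gammaln(r2 - (c1 - support) + 1)
        - (gammaln(n + 1) - gammaln(c1 + 1) - gammaln(n - c1 + 1))
    )
    return support, logpmf


def fisher_exact_2x2(
    table: ContingencyTable2x2, alternative: str = "two-sided", direction: str = ""
) -> EnrichmentResult:
    """Fisher's exact test on a 2x2 table with fixed margins.

    ``alternative`` is ``"two-sided"`` (minimum-likelihood rule),
    ``"greater"`` (association in the direction of larger ``a``) or
    ``"less"``.  The p-value is clipped to (0, 1].
    """
    support, logpmf = _log_pmf_family(table)
    obs = int(np.flatnonzero(support == table.a)[0])
    if alternative == "two-sided":
        cutoff = logpmf[obs] + math.log1p(_TWO_SIDED_RELTOL)
        p = float(np.exp(logpmf[logpmf <= cutoff]).sum())
    elif alternative == "greater":
        p = float(np.exp(logpmf[obs:]).sum())
    elif alternative == "less":
        p = float(np.exp(logpmf[: obs + 1]).sum())
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    p = min(p, 1.0)
    p = max(p, 5e-324)  # clip into (0, 1]
    return EnrichmentResult(table=table, odds_ratio=table.odds_ratio, pvalue=p, direction=direction)


def directional_enrichment(
    de_genes: set[str], background: set[str], annotation: CuratedAnnotation
) -> EnrichmentResult:
    """Protective-vs-Detrimental enrichment among DE genes.

    The 2x2 table counts DE / non-DE genes within the Protective and
    Detrimental annotation classes, restricted to the detected background;
    Ambiguous genes are excluded entirely.  Returns the two-sided exact
    test.
    """
    de = {g for g in de_genes}
    if not de <= background:
        raise ValidationError("de_genes must be a subset of the background")
    prot = annotation.genes_with("Protective") & background
    det = annotation.genes_with("Detrimental") & background
    if not prot and not det:
        raise DegenerateInputError("no Protective/Detrimental annotated genes in background")
    a = len(de & prot)
    c = len(de & det)
    table = ContingencyTable2x2(a=a, b=len(prot) - a, c=c, d=len(det) - c)
    return fisher_exact_2x2(table, "two-sided", direction="Protective vs Detrimental among DE")


def target_enrichment(
    up: set[str], down: set[str], targets: TargetGeneSet
) -> EnrichmentResult:
    """Predicted-target enrichment among up- vs downregulated genes."""
    if up & down:
        raise ValidationError("up and down gene sets must be disjoint")
    if not up and not down:
        raise DegenerateInputError("both up and down gene sets are empty")
    a = len(targets.genes & up)
    c = len(targets.genes & down)
    table = ContingencyTable2x2(a=a, b=len(up) - a, c=c, d=len(down) - c)
    return fisher_exact_2x2(
        table, "two-sided", direction=f"{targets.set_id} targets: up vs down"
    )
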