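"""Cosine-similarity search of a fold-change signature against a compendium.

The procedure mirrors connectivity-map-style signature matching for
skeletal transcriptomics: a query profile of log2 fold changes is compared
against every dataset in a compendium using cosine similarity over the
genes the two share, the resulting scores are standardized to z-scores
(standard deviations from the mean similarity across the compendium) and
ranked.  Similar responses score positive, opposite responses negative;
the z-scale makes queries comparable regardless of their raw score spread.

The query itself is never part of the background used for
standardization, and the z-scores are computed across exactly the set of
datasets that pass the minimum shared-gene filter.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateInputError
from .io import Compendium, FoldChangeProfile, normalize_symbol

#: default minimum number of shared genes for a dataset to be scored;
#: guards against spuriously extreme cosines on tiny intersections
DEFAULT_MIN_SHARED = 100


@dataclass(frozen=True)
class SimilarityResult:
    """One compendium dataset's similarity to the query."""

    dataset_id: str
    n_shared: int
    cosine: float
    zscore: float
    rank: int


@dataclass
class SearchOutcome:
    """Ranked similarity results plus the datasets excluded by the overlap filter."""

    results: list[SimilarityResult]
    skipped: list[tuple[str, int]]  # (dataset_id, n_shared) failing min_shared

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.rank, r.dataset_id, r.n_shared, r.cosine, r.zscore) for r in self.results],
            columns=["rank", "dataset_id", "n_shared", "cosine", "zscore"],
        )


def _as_series(v) -> pd.Series:
    if isinstance(v, FoldChangeProfile):
        return v.values
    if not isinstance(v, pd.Series):
        v = pd.Series(dict(v), dtype=float)
    # symbols are matched case-insensitively everywhere; normalize raw input
    s = v.astype(float)
    s.index = [normalize_symbol(g) for g in s.index]
    if s.index.has_duplicates:
        raise DegenerateInputError("duplicate gene symbols in query after normalization")
    return s


def cosine_similarity(u, v) -> tuple[float, int]:
    """Cosine similarity of two gene -> value mappings over their shared genes.

    Returns ``(cosine, n_shared)``.  Raises
    :class:`~oasig.errors.DegenerateInputError` when the gene intersection
    is empty or either restricted vector has zero norm — an undefined
    similarity is never silently reported as 0.
    """
    su, sv = _as_series(u), _as_series(v)
    shared = su.index.intersection(sv.index)
    if len(shared) == 0:
        raise DegenerateInputError("no shared genes between the two profiles")
    x = su.loc[shared].to_numpy()
    y = sv.loc[shared].to_numpy()
    sx, sy = float(np.dot(x, x)), float(np.dot(y, y))
    if sx == 0.0 or sy == 0.0:
        raise DegenerateInputError("zero-norm vector on the shared genes; cosine undefined")
    # single sqrt of the product keeps self-similarity exactly 1.0
    return float(np.dot(x, y) / math.sqrt(sx * sy)), int(len(shared))


def zscore_standardize(scores: Sequence[float]) -> np.ndarray:
    """Standardize scores to z-scores using the sample (n-1) standard deviation."""
    arr = np.asarray(scores, dtype=float)
    if arr.size < 2:
        raise DegenerateInputError("need at least 2 scores to standardize")
    sd = arr.std(ddof=1)
    if sd == 0.0:
        raise DegenerateInputError("constant scores; z-scores undefined")
    return (arr - arr.mean()) / sd


def compendium_search(
    query: FoldChangeProfile | pd.Series | Mapping[str, float],
    compendium: Compendium,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> SearchOutcome:
    """Rank every compendium dataset by similarity to the query signature.

    Datasets sharing fewer than ``min_shared`` genes with the query are
    reported in ``skipped`` and never scored; z-scores are computed across
    exactly the scored set.  Results are sorted by z descending with ties
    broken by dataset_id so ranks are reproducible bit-for-bit.
    """
    q = _as_series(query)
    if len(q) == 0:
        raise DegenerateInputError("empty query profile")
    # one aligned matrix (genes x datasets) so the 800-dataset case stays fast
    mat = pd.DataFrame({d: p.values for d, p in compendium.profiles.items()})
    mat = mat.reindex(mat.index.union(q.index))
    qv = q.reindex(mat.index).to_numpy()
    m = mat.to_numpy()
    valid = ~np.isnan(m) & ~np.isnan(qv)[:, None]
    n_shared = valid.sum(axis=0)
    mv = np.where(valid, m, 0.0)
    qm = np.where(valid, qv[:, None], 0.0)
    num = (mv * qm).sum(axis=0)
    den = np.linalg.norm(mv, axis=0) * np.linalg.norm(qm, axis=0)
    ids = np.array(mat.columns)
    ok = (n_shared >= min_shared) & (den > 0)
    skipped = sorted(zip(ids[~ok].tolist(), n_shared[~ok].astype(int).tolist()))
    if ok.sum() < 2:
        raise DegenerateInputError(
            f"fewer than 2 datasets share >= {min_shared} genes with the query"
        )
    cosines = num[ok] / den[ok]
    zs = zscore_standardize(cosines)
    order = sorted(
        range(int(ok.sum())), key=lambda i: (-zs[i], ids[ok][i])
    )
    results = [
        SimilarityResult(
            dataset_id=str(ids[ok][i]),
            n_shared=int(n_shared[ok][i]),
            cosine=float(cosines[i]),
            zscore=float(zs[i]),
            rank=rank,
        )
        for rank, i in enumerate(order, start=1)
    ]
    return SearchOutcome(results=results, skipped=skipped)


def rank_plot_table(
    results: Sequence[SimilarityResult], highlight: Iterable[str] = ()
) -> pd.DataFrame:
    """Rank-vs-z table ready for plotting, with a highlight flag column.

    Unknown highlight ids produce a warning, not a failure.
    """
    highlight = set(highlight)
    known = {r.dataset_id for r in results}
    unknown = highlight - known
    if unknown:
        warnings.warn(f"highlight id(s) not in results: {sorted(unknown)}", stacklevel=2)
    return pd.DataFrame(
        [
            (r.rank, r.dataset_id, r.zscore, r.dataset_id in highlight)
            for r in sorted(results, key=lambda r: r.rank)
        ],
        columns=["rank", "dataset_id", "zscore", "highlight"],
    )
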