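"""Data model and readers/writers for the comparison pipeline.

The pipeline consumes five kinds of plain-text inputs:

* differential-expression (DE) result tables — per gene: log2 fold change,
  p-value and Benjamini–Hochberg FDR, tab-separated with a header;
* fold-change profile compendia — a genes x datasets matrix of log2 fold
  changes (blank cell = gene not measured in that dataset) plus a metadata
  table mapping dataset ids to species and model labels;
* curated effect annotations labelling genes Protective / Detrimental /
  Ambiguous with respect to joint damage;
* predicted miRNA target gene sets in GMT format;
* one-to-one ortholog symbol maps for cross-species comparison.

Gene symbols are matched case-insensitively: every reader and constructor
uppercases symbols, so mouse ``Matn2`` and human ``MATN2`` collide onto the
same key.  All files are UTF-8, tab-separated, "." decimal point, header
mandatory.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import TableFormatError, TableParseError, ValidationError

ANNOTATION_LABELS = frozenset({"Protective", "Detrimental", "Ambiguous"})

#: canonical column names of a DE table
DE_COLUMNS = ("gene", "log2fc", "pvalue", "fdr")


def normalize_symbol(symbol: str) -> str:
    """Uppercase and strip a gene symbol for case-insensitive matching."""
    return str(symbol).strip().upper()


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class DETable:
    """One experiment's differential-expression results.

    ``frame`` has columns ``gene, log2fc, pvalue, fdr`` with unique,
    uppercased gene symbols, finite log2fc, pvalue in (0, 1] and fdr in
    [0, 1].  Row order is preserved from the source.
    """

    dataset_id: str
    species: str
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in DE_COLUMNS if c not in f.columns]
        if missing:
            raise TableFormatError(f"DE table missing column(s): {', '.join(missing)}")
        f = f.loc[:, list(DE_COLUMNS)].copy()
        f["gene"] = f["gene"].map(normalize_symbol)
        dup = f["gene"][f["gene"].duplicated()]
        if len(dup):
            raise ValidationError(f"duplicate gene symbol(s) in DE table: {sorted(set(dup))}")
        for col, lo, hi, lo_open in (
            ("pvalue", 0.0, 1.0, True),
            ("fdr", 0.0, 1.0, False),
        ):
            vals = f[col].to_numpy(float)
            bad = ~np.isfinite(vals) | (vals < lo) | (vals > hi)
            if lo_open:
                bad |= vals == lo
            if bad.any():
                g = f["gene"].to_numpy()[bad][0]
                raise ValidationError(f"{col} out of range for gene {g}")
        if not np.isfinite(f["log2fc"].to_numpy(float)).all():
            raise ValidationError("non-finite log2fc in DE table")
        object.__setattr__(self, "frame", f.reset_index(drop=True))

    @property
    def genes(self) -> set[str]:
        return set(self.frame["gene"])

    def __len__(self) -> int:
        return len(self.frame)


@dataclass
class FoldChangeProfile:
    """A single dataset's gene -> log2 fold change mapping."""

    dataset_id: str
    species: str = ""
    description: str = ""
    values: pd.Series = field(default_factory=lambda: pd.Series(dtype=float))

    def __post_init__(self) -> None:
        s = pd.Series(self.values, dtype=float)
        s.index = [normalize_symbol(g) for g in s.index]
        if s.index.has_duplicates:
            dups = sorted(set(s.index[s.index.duplicated()]))
            raise ValidationError(f"duplicate gene symbol(s) in profile {self.dataset_id}: {dups}")
        if not np.isfinite(s.to_numpy()).all():
            raise ValidationError(f"non-finite fold change in profile {self.dataset_id}")
        self.values = s

    @property
    def genes(self) -> set[str]:
        return set(self.values.index)

    def __len__(self) -> int:
        return len(self.values)


@dataclass
class Compendium:
    """A collection of fold-change profiles with per-dataset metadata.

    ``metadata`` maps dataset_id -> (species, model label).  Every profile
    must have a metadata entry and dataset ids must be unique.
    """

    profiles: dict[str, FoldChangeProfile]
    metadata: pd.DataFrame  # index dataset_id, columns species, model

    def __post_init__(self) -> None:
        for want in ("species", "model"):
            if want not in self.metadata.columns:
                raise TableFormatError(f"compendium metadata missing column: {want}")
        if self.metadata.index.has_duplicates:
            raise ValidationError("duplicate dataset_id in compendium metadata")
        missing = [d for d in self.profiles if d not in self.metadata.index]
        if missing:
            raise ValidationError(f"profiles without metadata: {missing[:5]}")

    def __len__(self) -> int:
        return len(self.profiles)

    def ids(self) -> list[str]:
        return list(self.profiles)


@dataclass
class CuratedAnnotation:
    """Gene -> effect label map (Protective / Detrimental / Ambiguous)."""

    entries: dict[str, str]

    def __post_init__(self) -> None:
        clean: dict[str, str] = {}
        for gene, label in self.entries.items():
            g = normalize_symbol(gene)
            if label not in ANNOTATION_LABELS:
                raise ValidationError(f"unknown annotation label {label!r} for gene {g}")
            if g in clean and clean[g] != label:
                raise ValidationError(f"gene {g} annotated with conflicting labels")
            clean[g] = label
        self.entries = clean

    def genes_with(self, label: str) -> set[str]:
        if label not in ANNOTATION_LABELS:
            raise ValidationError(f"unknown annotation label {label!r}")
        return {g for g, l in self.entries.items() if l == label}


@dataclass(frozen=True)
class TargetGeneSet:
    """A named gene set, e.g. the predicted targets of one miRNA."""

    set_id: str
    genes: frozenset[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValidationError(f"gene set {self.set_id!r} is empty")
        object.__setattr__(self, "genes", frozenset(normalize_symbol(g) for g in self.genes))

    def __len__(self) -> int:
        return len(self.genes)


@dataclass
class OrthologMap:
    """One-to-one gene symbol map between two species' namespaces."""

    pairs: dict[str, str]

    def __post_init__(self) -> None:
        clean = {normalize_symbol(s): normalize_symbol(t) for s, t in self.pairs.items()}
        if len(clean) != len(self.pairs):
            raise ValidationError("source symbol mapped more than once in ortholog map")
        targets = list(clean.values())
        if len(set(targets)) != len(targets):
            dups = sorted({t for t in targets if targets.count(t) > 1})
            raise ValidationError(f"target symbol(s) mapped from multiple sources: {dups}")
        self.pairs = clean

    def __len__(self) -> int:
        return len(self.pairs)


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"no such file: {path}")
    return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)


def _numeric(frame: pd.DataFrame, col: str, path: Path) -> pd.Series:
    """Parse a string column as float, citing the 1-based file line on failure."""
    parsed = pd.to_numeric(frame[col].replace("", np.nan), errors="coerce")
    raw_nonempty = frame[col].astype(str).str.strip() != ""
    bad = parsed.isna() & raw_nonempty
    if bad.any() or parsed.isna().any():
        # header is line 1, first data row is line 2
        idx = int(np.flatnonzero(parsed.isna())[0])
        raise TableParseError(
            f"{path}: cannot parse {col!r} value {frame[col].iloc[idx]!r} on line {idx + 2}"
        )
    return parsed.astype(float)


def read_de_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    dataset_id: str | None = None,
    species: str = "",
) -> DETable:
    """Read a tab-separated DE result table.

    ``dialect`` maps canonical column names (``gene, log2fc, pvalue, fdr``)
    to the file's column names; omitted keys default to the canonical name.
    """
    path = Path(path)
    raw = _read_tsv(path)
    dialect = dict(dialect or {})
    cols = {canon: dialect.get(canon, canon) for canon in DE_COLUMNS}
    missing = [src for src in cols.values() if src not in raw.columns]
    if missing:
        raise TableFormatError(f"{path}: missing required column(s): {', '.join(missing)}")
    frame = pd.DataFrame({"gene": raw[cols["gene"]]})
    for canon in ("log2fc", "pvalue", "fdr"):
        frame[canon] = _numeric(raw.rename(columns={cols[canon]: canon}), canon, path)
    return DETable(dataset_id=dataset_id or path.stem, species=species, frame=frame)


def write_de_table(table: DETable, path: str | Path) -> None:
    table.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")


def significant_sets(
    table: DETable, fold_threshold: float = 1.5, fdr_threshold: float = 0.05
) -> tuple[set[str], set[str]]:
    """Split a DE table into significantly up/down-regulated gene sets.

    A gene is up if ``log2fc >= log2(fold_threshold)`` and
    ``fdr <= fdr_threshold`` (both inclusive, mirroring the usual
    ">=1.5-fold, FDR<=0.05" rule); down analogously with
    ``log2fc <= -log2(fold_threshold)``.  ``fold_threshold`` is on the
    linear scale and must be >= 1.
    """
    if fold_threshold < 1:
        raise ValidationError("fold_threshold must be >= 1 (linear scale)")
    cut = math.log2(fold_threshold)
    f = table.frame
    sig = f["fdr"].to_numpy() <= fdr_threshold
    lfc = f["log2fc"].to_numpy()
    genes = f["gene"].to_numpy()
    up = set(genes[sig & (lfc >= cut) & (lfc > 0 if cut == 0 else True)])
    down = set(genes[sig & (lfc <= -cut) & (lfc < 0 if cut == 0 else True)])
    return up, down


def map_orthologs(obj, omap: OrthologMap):
    """Re-key a profile or DE table through a one-to-one ortholog map.

    Genes present in the map are renamed to their orthologs; genes absent
    are dropped.  Returns ``(mapped_object, n_dropped)``.  Raises
    :class:`ValidationError` if nothing survives (disjoint namespaces).
    """
    if isinstance(obj, FoldChangeProfile):
        keep = [g for g in obj.values.index if g in omap.pairs]
        dropped = len(obj.values) - len(keep)
        if not keep:
            raise ValidationError("ortholog map shares no genes with the profile")
        vals = obj.values.loc[keep]
        vals.index = [omap.pairs[g] for g in keep]
        out = FoldChangeProfile(obj.dataset_id, obj.species, obj.description, vals)
        return out, dropped
    if isinstance(obj, DETable):
        mask = obj.frame["gene"].isin(omap.pairs)
        dropped = int((~mask).sum())
        if not mask.any():
            raise ValidationError("ortholog map shares no genes with the DE table")
        frame = obj.frame[mask].copy()
        frame["gene"] = frame["gene"].map(omap.pairs)
        return DETable(obj.dataset_id, obj.species, frame), dropped
    raise TypeError(f"cannot ortholog-map object of type {type(obj).__name__}")


def read_gmt(path: str | Path) -> list[TargetGeneSet]:
    """Read gene sets from a GMT file (name, description, members per line)."""
    path = Path(path)
    if not path.exists():
        raise TableFormatError(f"no such file: {path}")
    sets: list[TargetGeneSet] = []
    for lineno, line in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        fields = line.rstrip("\n").split("\t")
        if len(fields) < 3:
            raise TableParseError(f"{path}: ragged GMT line {lineno} (need name, description, >=1 gene)")
        name, desc, *genes = fields
        genes = [g for g in genes if g.strip()]
        if not genes:
            raise TableParseError(f"{path}: ragged GMT line {lineno} (no gene members)")
        sets.append(TargetGeneSet(set_id=name, description=desc, genes=frozenset(genes)))
    return sets


def write_gmt(sets: Iterable[TargetGeneSet], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for s in sets:
            fh.write("\t".join([s.set_id, s.description, *sorted(s.genes)]) + "\n")


def read_annotation(path: str | Path) -> CuratedAnnotation:
    """Read a curated annotation TSV with columns ``gene`` and ``label``."""
    raw = _read_tsv(path)
    for col in ("gene", "label"):
        if col not in raw.columns:
            raise TableFormatError(f"{path}: missing required column: {col}")
    return CuratedAnnotation(dict(zip(raw["gene"], raw["label"])))


def write_annotation(annotation: CuratedAnnotation, path: str | Path) -> None:
    pd.DataFrame(
        sorted(annotation.entries.items()), columns=["gene", "label"]
    ).to_csv(path, sep="\t", index=False)


def read_ortholog_map(path: str | Path) -> OrthologMap:
    """Read a two-column (source, target) ortholog symbol map."""
    raw = _read_tsv(path)
    if raw.shape[1] < 2:
        raise TableFormatError(f"{path}: ortholog map needs two columns (source, target)")
    src, tgt = raw.columns[:2]
    return OrthologMap(dict(zip(raw[src], raw[tgt])))


def write_ortholog_map(omap: OrthologMap, path: str | Path) -> None:
    pd.DataFrame(sorted(omap.pairs.items()), columns=["source", "target"]).to_csv(
        path, sep="\t", index=False
    )


def read_profile_matrix(matrix_path: str | Path, metadata_path: str | Path) -> Compendium:
    """Read a genes x datasets fold-change matrix plus its metadata table.

    Blank cells mean the gene was not measured in that dataset and are
    dropped from the corresponding profile.
    """
    matrix_path = Path(matrix_path)
    raw = _read_tsv(matrix_path)
    if raw.shape[1] < 2:
        raise TableFormatError(f"{matrix_path}: profile matrix needs a gene column plus datasets")
    gene_col = raw.columns[0]
    genes = [normalize_symbol(g) for g in raw[gene_col]]
    meta_raw = _read_tsv(metadata_path)
    for col in ("dataset_id", "species", "model"):
        if col not in meta_raw.columns:
            raise TableFormatError(f"{metadata_path}: missing required column: {col}")
    meta = meta_raw.set_index("dataset_id")[["species", "model"]]
    profiles: dict[str, FoldChangeProfile] = {}
    for ds in raw.columns[1:]:
        vals = pd.to_numeric(raw[ds].replace("", np.nan), errors="coerce")
        strs = raw[ds].astype(str).str.strip()
        bad = vals.isna() & (strs != "") & (strs.str.lower() != "nan")
        if bad.any():
            idx = int(np.flatnonzero(bad)[0])
            raise TableParseError(
                f"{matrix_path}: cannot parse value {raw[ds].iloc[idx]!r} on line {idx + 2}"
            )
        series = pd.Series(vals.to_numpy(float), index=genes).dropna()
        species = meta["species"].get(ds, "") if ds in meta.index else ""
        profiles[ds] = FoldChangeProfile(ds, species=str(species), values=series)
    return Compendium(profiles=profiles, metadata=meta)


def write_profile_matrix(
    compendium: Compendium, matrix_path: str | Path, metadata_path: str | Path
) -> None:
    frame = pd.DataFrame({d: p.values for d, p in compendium.profiles.items()})
    frame.index.name = "gene"
    frame.sort_index().to_csv(matrix_path, sep="\t", float_format="%.10g", na_rep="")
    meta = compendium.metadata.copy()
    meta.index.name = "dataset_id"
    meta.to_csv(metadata_path, sep="\t")
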