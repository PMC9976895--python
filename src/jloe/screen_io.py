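"""Readers, writers and screen quality control for BF-matrix pipelines.

The universal input is a gene x screen matrix of log2 Bayes factors as
produced by a BAGEL-style essentiality classifier: tab-separated text, first
column gene symbols, header row of screen / cell-line identifiers. Companion
tables are a screen -> tissue annotation, gold-standard essential and
nonessential gene lists (one symbol per line), and an optional gene x
cell-line log2(TPM) expression matrix.

Screen quality is scored by the F-measure — the harmonic mean of precision
and recall against the gold-standard reference sets at a fixed BF cutoff
(default 5) — and screens below an F-measure threshold (default 0.80) are
dropped before analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "ScreenAnnotation",
    "GeneSet",
    "read_bf_matrix",
    "write_bf_matrix",
    "read_expression_matrix",
    "read_annotation",
    "write_annotation",
    "read_gene_set",
    "write_gene_set",
    "f_measure_qc",
    "qc_all_screens",
    "filter_screens",
    "hit_matrix",
]


@dataclass
class ScreenAnnotation:
    """Per-screen tissue labels and (optionally) QC F-measures."""

    table: pd.DataFrame  # index: screen_id; columns: tissue [, f_measure]

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dups = self.table.index[self.table.index.duplicated()].tolist()
            raise ValueError(f"duplicate screen ids in annotation: {dups}")
        if "tissue" not in self.table.columns:
            raise ValueError("annotation must have a 'tissue' column")

    @property
    def screen_ids(self) -> list[str]:
        return list(self.table.index)

    def tissue_of(self, screen_id: str) -> str:
        return str(self.table.loc[screen_id, "tissue"])

    def screens_for_tissue(self, tissue: str) -> list[str]:
        return list(self.table.index[self.table["tissue"] == tissue])

    @property
    def tissues(self) -> list[str]:
        return sorted(self.table["tissue"].unique())

    @property
    def f_measure(self) -> pd.Series | None:
        if "f_measure" in self.table.columns:
            return self.table["f_measure"]
        return None

    def with_f_measure(self, f: pd.Series) -> "ScreenAnnotation":
        table = self.table.copy()
        table["f_measure"] = f.reindex(table.index)
        return ScreenAnnotation(table)


@dataclass(frozen=True)
class GeneSet:
    """A labelled set of gene symbols."""

    label: str
    members: frozenset[str]

    def __init__(self, label: str, members) -> None:
        object.__setattr__(self, "label", label)
        object.__setattr__(self, "members", frozenset(str(m) for m in members))

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __iter__(self):
        return iter(sorted(self.members))


def _read_table(path, index_name: str) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep="\t", index_col=0, dtype={0: str})
    df.index = df.index.astype(str)
    df.index.name = index_name
    return df


def read_bf_matrix(
    path,
    *,
    transpose: bool = False,
    drop_missing_genes: bool = False,
) -> pd.DataFrame:
    """Read a gene x screen log2-BF matrix from tab-separated text.

    Parameters
    ----------
    path
        TSV file: first column gene symbols, header of screen ids.
    transpose
        Set when the file is oriented screens x genes.
    drop_missing_genes
        Drop genes with any missing value instead of raising. The per-tissue
        gene universe is the set of genes scored in every screen, so partial
        rows cannot be used downstream.
    """
    df = _read_table(path, "gene")
    if transpose:
        df = df.T
        df.index.name = "gene"
    if df.index.has_duplicates:
        dups = sorted(set(df.index[df.index.duplicated()]))
        raise ValueError(f"duplicate gene rows in {path}: {dups}")
    if df.columns.has_duplicates:
        dups = sorted(set(df.columns[df.columns.duplicated()]))
        raise ValueError(f"duplicate screen columns in {path}: {dups}")
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
            raise ValueError(
                f"non-numeric BF values in column {col!r} of {path} "
                f"at genes {bad.index.tolist()[:5]}"
            )
    if df.isna().any().any():
        if drop_missing_genes:
            df = df.dropna(axis=0, how="any")
        else:
            n = int(df.isna().sum().sum())
            raise ValueError(
                f"{n} missing BF values in {path}; pass drop_missing_genes=True "
                "to restrict to genes scored in every screen"
            )
    return df.astype(float)


def write_bf_matrix(df: pd.DataFrame, path) -> None:
    """Write a gene x screen matrix as TSV (genes as rows)."""
    out = df.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_expression_matrix(path, *, transpose: bool = False) -> pd.DataFrame:
    """Read a gene x cell-line log2(TPM) matrix; same dialect as the BF matrix."""
    return read_bf_matrix(path, transpose=transpose)


def read_annotation(path) -> ScreenAnnotation:
    """Read a screen -> tissue annotation TSV (columns: screen, tissue[, f_measure])."""
    df = _read_table(path, "screen")
    return ScreenAnnotation(df)


def write_annotation(annotation: ScreenAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t")


def read_gene_set(path, label: str | None = None) -> GeneSet:
    """Read a plain-text gene list, one symbol per line; '#' comments allowed."""
    path = Path(path)
    genes = []
    for line in path.read_text().splitlines():
        line = line.strip()
        if line and not line.startswith("#"):
            genes.append(line)
    return GeneSet(label or path.stem, genes)


def write_gene_set(gene_set: GeneSet, path) -> None:
    Path(path).write_text("".join(f"{g}\n" for g in gene_set))


def f_measure_qc(
    bf_column: pd.Series,
    essentials: GeneSet,
    nonessentials: GeneSet,
    bf_cutoff: float = 5.0,
) -> float:
    """F-measure of one screen against gold-standard reference sets.

    Among reference genes present in the column, genes at BF >= ``bf_cutoff``
    are predicted essential; precision and recall are computed on the
    resulting confusion matrix and their harmonic mean returned (0 when
    precision + recall is 0).
    """
    overlap = essentials.members & nonessentials.members
    if overlap:
        raise ValueError(
            f"reference sets overlap: {sorted(overlap)[:5]}"
            + ("..." if len(overlap) > 5 else "")
        )
    ess = bf_column.reindex(sorted(essentials.members)).dropna()
    non = bf_column.reindex(sorted(nonessentials.members)).dropna()
    if ess.empty or non.empty:
        raise ValueError(
            "screen column must contain at least one gene from each reference set"
        )
    tp = int((ess >= bf_cutoff).sum())
    fn = len(ess) - tp
    fp = int((non >= bf_cutoff).sum())
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    if precision + recall == 0.0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def qc_all_screens(
    matrix: pd.DataFrame,
    essentials: GeneSet,
    nonessentials: GeneSet,
    bf_cutoff: float = 5.0,
) -> pd.Series:
    """F-measure for every screen column of a BF matrix."""
    return pd.Series(
        {s: f_measure_qc(matrix[s], essentials, nonessentials, bf_cutoff) for s in matrix.columns},
        name="f_measure",
    )


def filter_screens(
    matrix: pd.DataFrame,
    annotation: ScreenAnnotation,
    min_f: float = 0.80,
) -> pd.DataFrame:
    """Retain screens whose annotated F-measure is >= ``min_f`` (inclusive)."""
    f = annotation.f_measure
    if f is None:
        raise ValueError("annotation carries no f_measure column; run QC first")
    f = f.reindex(matrix.columns)
    if f.isna().any():
        missing = f.index[f.isna()].tolist()
        raise ValueError(f"screens without an F-measure: {missing}")
    keep = [s for s in matrix.columns if f[s] >= min_f]
    if not keep:
        warnings.warn("no screens pass the F-measure threshold", stacklevel=2)
    return matrix[keep]


def hit_matrix(matrix: pd.DataFrame, hit_threshold: float = 10.0) -> pd.DataFrame:
    """Boolean gene x screen matrix of plain hits (BF >= threshold, inclusive)."""
    return matrix >= hit_threshold
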