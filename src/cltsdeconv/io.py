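"""Shared data model and readers/writers for expression matrices and tables.

The canonical in-memory orientation is genes x columns (cells or bulk
samples).  Matrices are stored dense as float64 regardless of the on-disk
layout; the ``unit`` tag, not the dtype, records what the numbers mean.
Gene and column identifiers are matched by exact, case-sensitive string
comparison.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

#: Recognized unit tags for an ExpressionMatrix.
UNITS = frozenset(
    {"raw_count", "CP10K", "CPM", "CLTS", "RPK", "TPM", "raw_bulk"}
)

#: Unit tags whose per-column sums have been equalized (transcriptome-size
#: information destroyed); using these as a deconvolution reference causes
#: Type-I issues.
SIZE_EQUALIZED_UNITS = frozenset({"CP10K", "CPM", "TPM"})


@dataclass
class ExpressionMatrix:
    """A genes x columns nonnegative expression matrix.

    Parameters
    ----------
    values : ndarray, shape (n_genes, n_columns)
        Expression values; absent entries are 0, never NaN.
    gene_ids : list of str
        Row identifiers, unique.
    column_ids : list of str
        Column identifiers (cell barcodes or bulk sample names), unique.
    unit : str
        One of ``UNITS``; carried through every transformation.
    """

    values: np.ndarray
    gene_ids: list[str]
    column_ids: list[str]
    unit: str = "raw_count"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if scipy.sparse.issparse(self.values):  # pragma: no cover - asarray densifies
            self.values = self.values.toarray()
        self.gene_ids = [str(g) for g in self.gene_ids]
        self.column_ids = [str(c) for c in self.column_ids]
        if self.values.ndim != 2:
            raise ValueError("expression values must be a 2-D matrix")
        if self.values.shape != (len(self.gene_ids), len(self.column_ids)):
            raise ValueError(
                f"shape {self.values.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.column_ids)} columns"
            )
        _check_unique(self.gene_ids, "gene")
        _check_unique(self.column_ids, "column")
        if self.unit not in UNITS:
            raise ValueError(f"unknown unit {self.unit!r}; expected one of {sorted(UNITS)}")
        if np.isnan(self.values).any():
            raise ValueError("expression matrix contains NaN entries")
        if (self.values < 0).any():
            raise ValueError("expression matrix contains negative entries")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_columns(self) -> int:
        return len(self.column_ids)

    def gene_index(self) -> pd.Index:
        return pd.Index(self.gene_ids)

    def column_sums(self) -> np.ndarray:
        return self.values.sum(axis=0)

    def with_values(self, values: np.ndarray, unit: str | None = None) -> "ExpressionMatrix":
        """Copy with new values (and optionally a new unit tag)."""
        return ExpressionMatrix(
            values=values,
            gene_ids=list(self.gene_ids),
            column_ids=list(self.column_ids),
            unit=self.unit if unit is None else unit,
        )

    def subset_genes(self, gene_ids: list[str]) -> "ExpressionMatrix":
        idx = self.gene_index().get_indexer(gene_ids)
        if (idx < 0).any():
            missing = [g for g, i in zip(gene_ids, idx) if i < 0]
            raise KeyError(f"genes absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.values[idx, :], list(gene_ids), list(self.column_ids), self.unit)

    def subset_columns(self, column_ids: list[str]) -> "ExpressionMatrix":
        idx = pd.Index(self.column_ids).get_indexer(column_ids)
        if (idx < 0).any():
            missing = [c for c, i in zip(column_ids, idx) if i < 0]
            raise KeyError(f"columns absent from matrix: {missing[:10]}")
        return ExpressionMatrix(self.values[:, idx], list(self.gene_ids), list(column_ids), self.unit)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_ids, columns=self.column_ids)


@dataclass
class CellAnnotation:
    """Maps each cell to a sample ID and a cell-type label."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"cell", "sample", "cell_type"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"annotation missing columns: {sorted(missing)}")
        t = self.table.loc[:, ["cell", "sample", "cell_type"]].astype(str)
        dup = t["cell"][t["cell"].duplicated()]
        if len(dup):
            raise ValueError(f"duplicate cell IDs in annotation: {sorted(set(dup))[:10]}")
        if (t["cell_type"].str.len() == 0).any() or t["cell_type"].isin(["nan"]).any():
            raise ValueError("empty cell-type labels in annotation")
        self.table = t.reset_index(drop=True)

    @property
    def cells(self) -> list[str]:
        return self.table["cell"].tolist()

    @property
    def samples(self) -> list[str]:
        return sorted(self.table["sample"].unique())

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.table["cell_type"].unique())

    def subset(self, cells: list[str]) -> "CellAnnotation":
        keep = self.table[self.table["cell"].isin(set(cells))]
        return CellAnnotation(keep.copy())


@dataclass
class GeneLengthTable:
    """Gene -> RNA length in bases."""

    lengths: pd.Series = field(repr=False)  # index gene_id, values int

    def __post_init__(self) -> None:
        s = self.lengths
        if isinstance(s, pd.DataFrame):
            s = s.set_index("gene_id")["length"]
        s = s.astype(float)
        s.index = s.index.astype(str)
        if s.index.duplicated().any():
            dups = sorted(set(s.index[s.index.duplicated()]))
            raise ValueError(f"duplicate gene IDs in length table: {dups[:10]}")
        if (s <= 0).any():
            raise ValueError("gene lengths must be positive")
        self.lengths = s

    def get(self, gene_ids: list[str], policy: str = "error") -> pd.Series:
        """Lengths for ``gene_ids``; missing genes are an error by default.

        policy="drop" returns only the genes present.
        """
        present = self.lengths.reindex(gene_ids)
        missing = present.index[present.isna()]
        if len(missing):
            if policy == "error":
                raise KeyError(
                    f"genes absent from gene-length table: {sorted(missing)[:10]}"
                )
            if policy == "drop":
                return present.dropna()
            raise ValueError(f"unknown missing-length policy {policy!r}")
        return present


@dataclass
class GroundTruthFractions:
    """True cell-type fractions per mixture; rows (mixture_id, cell_type, fraction)."""

    table: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        required = {"mixture_id", "cell_type", "fraction"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"truth table missing columns: {sorted(missing)}")
        t = self.table.copy()
        t["mixture_id"] = t["mixture_id"].astype(str)
        t["cell_type"] = t["cell_type"].astype(str)
        t["fraction"] = t["fraction"].astype(float)
        sums = t.groupby("mixture_id")["fraction"].sum()
        bad = sums[(sums - 1.0).abs() > 1e-9]
        if len(bad):
            raise ValueError(
                f"fractions do not sum to 1 for mixtures: {bad.index.tolist()[:5]}"
            )
        self.table = t.reset_index(drop=True)

    def pivot(self) -> pd.DataFrame:
        """mixtures x cell_types matrix of fractions."""
        return self.table.pivot(index="mixture_id", columns="cell_type", values="fraction").fillna(0.0)


def _check_unique(ids: list[str], kind: str) -> None:
    seen: set[str] = set()
    dups: set[str] = set()
    for x in ids:
        if x in seen:
            dups.add(x)
        seen.add(x)
    if dups:
        raise ValueError(f"duplicate {kind} IDs: {sorted(dups)[:10]}")


# ---------------------------------------------------------------------------
# Readers / writers


def read_expression(
    path,
    *,
    layout: str = "genes_by_columns",
    unit: str = "raw_count",
    features=None,
    barcodes=None,
) -> ExpressionMatrix:
    """Read an expression matrix from a dense TSV or an MTX triplet.

    Parameters
    ----------
    path : str or Path
        Dense delimited table (first column gene_id, header of column IDs)
        or a Matrix Market ``.mtx`` file; the latter requires ``features``
        and ``barcodes`` sidecar paths (or ``<dir>/features.tsv`` and
        ``<dir>/barcodes.tsv`` next to the matrix).
    layout : {"genes_by_columns", "columns_by_genes"}
        Orientation of the file on disk; the returned matrix is always
        genes x columns.
    unit : str
        Unit tag to attach (default ``raw_count``).
    """
    path = os.fspath(path)
    if path.endswith(".mtx"):
        d = os.path.dirname(path)
        features = features or os.path.join(d, "features.tsv")
        barcodes = barcodes or os.path.join(d, "barcodes.tsv")
        m = scipy.io.mmread(path)
        values = np.asarray(m.todense() if scipy.sparse.issparse(m) else m, dtype=np.float64)
        genes = pd.read_csv(features, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
        cols = pd.read_csv(barcodes, sep="\t", header=None).iloc[:, 0].astype(str).tolist()
        if layout == "columns_by_genes":
            values = values.T
            genes, cols = genes, cols  # sidecars always name genes/columns
        if values.shape[0] != len(genes) or values.shape[1] != len(cols):
            raise ValueError(
                f"MTX shape {values.shape} does not match sidecars "
                f"({len(genes)} features, {len(cols)} barcodes)"
            )
        return ExpressionMatrix(values, genes, cols, unit)
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    if layout == "columns_by_genes":
        df = df.T
    return ExpressionMatrix(df.to_numpy(dtype=np.float64), df.index.tolist(), df.columns.tolist(), unit)


def write_expression(matrix: ExpressionMatrix, path, *, format: str = "tsv") -> None:
    """Write a matrix as dense TSV or MTX triplet; round-trips through read_expression."""
    if matrix.n_genes == 0 or matrix.n_columns == 0:
        raise ValueError("refusing to write an empty expression matrix")
    path = os.fspath(path)
    if format == "tsv":
        matrix.to_frame().to_csv(path, sep="\t", float_format="%.12g")
    elif format == "mtx":
        d = os.path.dirname(path)
        sp = scipy.sparse.coo_matrix(matrix.values)
        scipy.io.mmwrite(path, sp)
        pd.Series(matrix.gene_ids).to_csv(
            os.path.join(d, "features.tsv"), sep="\t", header=False, index=False
        )
        pd.Series(matrix.column_ids).to_csv(
            os.path.join(d, "barcodes.tsv"), sep="\t", header=False, index=False
        )
    else:
        raise ValueError(f"unknown format {format!r}; use 'tsv' or 'mtx'")


def read_annotation(path) -> CellAnnotation:
    """Read a cell annotation TSV with columns cell, sample, cell_type."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    return CellAnnotation(df)


def write_annotation(annotation: CellAnnotation, path) -> None:
    annotation.table.to_csv(path, sep="\t", index=False)


def read_gene_lengths(path) -> GeneLengthTable:
    """Read a gene-length TSV with columns gene_id, length."""
    df = pd.read_csv(path, sep="\t")
    return GeneLengthTable(df.set_index(df.columns[0]).iloc[:, 0])


def write_gene_lengths(lengths: GeneLengthTable, path) -> None:
    lengths.lengths.rename("length").rename_axis("gene_id").to_csv(path, sep="\t")


def pair(matrix: ExpressionMatrix, annotation: CellAnnotation):
    """Restrict a matrix to annotated cells (and the annotation to matrix cells).

    Returns (matrix, annotation) with matching column order.
    """
    cells = [c for c in annotation.cells if c in set(matrix.column_ids)]
    if not cells:
        raise ValueError("no annotated cells present in the expression matrix")
    return matrix.subset_columns(cells), annotation.subset(cells)
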