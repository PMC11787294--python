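"""Deconvolution reference: per-gene, per-cell-type expression mean and variance.

The reference must be built from raw counts (single-sample data) or CLTS-
normalized counts (multi-sample): both preserve between-cell-type
transcriptome-size differences.  Size-equalized units (CP10K/CPM/TPM) are
rejected because they bias the estimated fractions toward large-
transcriptome types (Type-I issues); the guard can be overridden only to
study that bias deliberately.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import SIZE_EQUALIZED_UNITS, CellAnnotation, ExpressionMatrix, pair
from .signatures import SignatureSet

logger = logging.getLogger(__name__)

#: Relative variance floor: sigma2 entries below VAR_FLOOR_REL * mu^2 are
#: raised to it before likelihood evaluation (zero-variance singularities).
VAR_FLOOR_REL = 1e-12


@dataclass
class ReferenceProfile:
    """Signature-gene expression means and variances per cell type.

    ``mu`` and ``sigma2`` are m x n matrices (m signature genes, the union
    over cell types; n cell types): the sample mean and unbiased (ddof=1)
    variance of each gene over all cells of each type, pooled across
    samples.
    """

    gene_ids: list[str]
    cell_types: list[str]
    mu: np.ndarray = field(repr=False)
    sigma2: np.ndarray = field(repr=False)
    source_unit: str = "raw_count"
    n_cells: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.mu = np.asarray(self.mu, dtype=float)
        self.sigma2 = np.asarray(self.sigma2, dtype=float)
        m, n = len(self.gene_ids), len(self.cell_types)
        if self.mu.shape != (m, n) or self.sigma2.shape != (m, n):
            raise ValueError("mu/sigma2 shapes do not match gene and cell-type lists")
        if (self.sigma2 < 0).any():
            raise ValueError("negative variances in reference")
        if (self.mu.max(axis=0) <= 0).any():
            bad = [t for j, t in enumerate(self.cell_types) if self.mu[:, j].max() <= 0]
            raise ValueError(f"cell types with no positive mean expression: {bad}")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def floored_sigma2(self) -> np.ndarray:
        """sigma2 with the relative floor applied (for likelihood evaluation)."""
        floor = VAR_FLOOR_REL * self.mu**2
        n_raised = int((self.sigma2 < floor).sum())
        if n_raised:
            logger.debug("variance floor raised %d reference entries", n_raised)
        return np.maximum(self.sigma2, floor)

    def scale_types(self, factors: np.ndarray) -> "ReferenceProfile":
        """Multiply each cell type's mean column by a factor (variance by its
        square) — the analytic device behind the Type-I bias prediction."""
        factors = np.asarray(factors, dtype=float)
        if (factors <= 0).any():
            raise ValueError("scale factors must be positive")
        return ReferenceProfile(
            gene_ids=list(self.gene_ids),
            cell_types=list(self.cell_types),
            mu=self.mu * factors,
            sigma2=self.sigma2 * factors**2,
            source_unit=self.source_unit,
            n_cells=dict(self.n_cells),
        )

    def write(self, prefix) -> None:
        """Serialize as <prefix>.means.tsv, <prefix>.variances.tsv, <prefix>.meta.tsv."""
        pd.DataFrame(self.mu, index=self.gene_ids, columns=self.cell_types).to_csv(
            f"{prefix}.means.tsv", sep="\t", float_format="%.12g")
        pd.DataFrame(self.sigma2, index=self.gene_ids, columns=self.cell_types).to_csv(
            f"{prefix}.variances.tsv", sep="\t", float_format="%.12g")
        meta = pd.DataFrame({
            "cell_type": self.cell_types,
            "n_cells": [self.n_cells.get(t, 0) for t in self.cell_types],
        })
        meta.insert(0, "source_unit", self.source_unit)
        meta.to_csv(f"{prefix}.meta.tsv", sep="\t", index=False)

    @classmethod
    def read(cls, prefix) -> "ReferenceProfile":
        mu = pd.read_csv(f"{prefix}.means.tsv", sep="\t", index_col=0)
        sigma2 = pd.read_csv(f"{prefix}.variances.tsv", sep="\t", index_col=0)
        meta = pd.read_csv(f"{prefix}.meta.tsv", sep="\t")
        return cls(
            gene_ids=mu.index.astype(str).tolist(),
            cell_types=mu.columns.astype(str).tolist(),
            mu=mu.to_numpy(float),
            sigma2=sigma2.to_numpy(float),
            source_unit=str(meta["source_unit"].iloc[0]),
            n_cells=dict(zip(meta["cell_type"].astype(str), meta["n_cells"].astype(int))),
        )


def build_reference(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    signatures: SignatureSet,
    *,
    allow_size_equalized: bool = False,
) -> ReferenceProfile:
    """Build the reference over the signature-gene union.

    ``matrix`` must be CLTS (multi-sample) or raw counts (single sample);
    CP10K/CPM/TPM are rejected (Type-I hazard) unless
    ``allow_size_equalized`` is set for deliberate issue-injection studies.
    """
    if matrix.unit in SIZE_EQUALIZED_UNITS and not allow_size_equalized:
        raise ValueError(
            f"reference unit {matrix.unit!r} is size-equalized and would introduce "
            "Type-I issues; use raw counts (single sample) or CLTS (multi-sample), "
            "or set allow_size_equalized=True to study the bias deliberately"
        )
    matrix, annotation = pair(matrix, annotation)
    gene_union = signatures.union()
    sub = matrix.subset_genes(gene_union)
    by_cell = annotation.table.set_index("cell")["cell_type"]
    labels = by_cell.reindex(sub.column_ids).to_numpy()
    types = signatures.cell_types
    mu = np.empty((len(gene_union), len(types)))
    sigma2 = np.empty_like(mu)
    n_cells: dict[str, int] = {}
    for j, t in enumerate(types):
        cols = np.flatnonzero(labels == t)
        if cols.size < 2:
            raise ValueError(f"cell type {t!r} has {cols.size} < 2 cells in the matrix")
        block = sub.values[:, cols]
        mu[:, j] = block.mean(axis=1)
        sigma2[:, j] = block.var(axis=1, ddof=1)
        n_cells[t] = int(cols.size)
    return ReferenceProfile(
        gene_ids=gene_union,
        cell_types=list(types),
        mu=mu,
        sigma2=sigma2,
        source_unit=matrix.unit,
        n_cells=n_cells,
    )
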