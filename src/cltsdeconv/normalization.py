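"""Transcriptome-size computation and CLTS normalization.

CLTS (Count based on Linearized Transcriptome Size) rescales each sample
by a fitted linear map of its cell-type mean transcriptome sizes onto a
baseline sample, so that after normalization the same cell type has a
similar mean size in every sample while *different* cell types keep their
genuine size differences.  This is the property that CP10K/CPM destroy:
equalizing every cell's column sum erases the biological multi-fold size
differences between cell types, which later biases deconvolution
(Type-I issues).

For sample ``i`` with per-type mean sizes ``x_ij`` and baseline sizes
``x_1j`` the fit is ``x_ij = a_i * x_1j + b_i`` (ordinary least squares
over shared cell types; the baseline gets ``a=1, b=0`` exactly).  With
``v_max = max_i b_i/a_i``, every entry ``u`` of a cell in sample ``i`` is
updated to ``u/a_i + (v_max - b_i/a_i)/G`` where ``G`` is the number of
genes; the uniform per-gene shift keeps all values nonnegative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .io import CellAnnotation, ExpressionMatrix, GeneLengthTable, pair

logger = logging.getLogger(__name__)


@dataclass
class TranscriptomeSizeTable:
    """Mean measured transcriptome size per (sample, cell type) group.

    ``mean_size`` is the arithmetic mean of per-cell column sums of the raw
    count matrix over the group's cells; ``n_cells`` the group size.
    """

    table: pd.DataFrame = field(repr=False)  # columns: sample, cell_type, mean_size, n_cells

    def __post_init__(self) -> None:
        required = {"sample", "cell_type", "mean_size", "n_cells"}
        if required - set(self.table.columns):
            raise ValueError(f"size table missing columns {required - set(self.table.columns)}")
        self.table = self.table.reset_index(drop=True)

    @property
    def samples(self) -> list[str]:
        return sorted(self.table["sample"].unique())

    def pivot(self) -> pd.DataFrame:
        """samples x cell_types matrix of mean sizes (NaN where absent)."""
        return self.table.pivot(index="sample", columns="cell_type", values="mean_size")


@dataclass
class CltsModel:
    """Fitted CLTS coefficients.

    Per-sample linear coefficients mapping baseline cell-type mean sizes to
    that sample's (``x_ij = a_i x_1j + b_i``), the global shift ``v_max``
    and the gene count ``G`` used for the per-gene shift.
    """

    baseline_sample: str
    coefficients: dict[str, tuple[float, float]]  # sample -> (a, b)
    v_max: float
    G: int

    def __post_init__(self) -> None:
        a1, b1 = self.coefficients[self.baseline_sample]
        if (a1, b1) != (1.0, 0.0):
            raise ValueError("baseline sample must have coefficients (1, 0)")
        for s, (a, _b) in self.coefficients.items():
            if a <= 0:
                raise ValueError(f"sample {s!r} has nonpositive slope a={a}")
        ratios = [b / a for a, b in self.coefficients.values()]
        if abs(self.v_max - max(ratios)) > 1e-9 * max(1.0, abs(self.v_max)):
            raise ValueError("v_max must equal max over samples of b_i/a_i")


@dataclass
class MergeAdvisory:
    """Which samples could be merged under a size-correlation threshold."""

    threshold: float
    pairwise_correlations: pd.DataFrame = field(repr=False)
    merge_groups: list[list[str]] = field(default_factory=list)
    suggested_baseline: str = ""

    def to_text(self) -> str:
        lines = [
            "Sample merge advisory",
            f"correlation threshold: {self.threshold}",
            "",
            "pairwise Pearson r of shared cell-type mean transcriptome sizes:",
            self.pairwise_correlations.to_string(float_format=lambda v: f"{v:.4f}"),
            "",
            "proposed merge groups:",
        ]
        for g in self.merge_groups:
            lines.append("  " + ", ".join(g))
        lines.append(f"suggested baseline sample: {self.suggested_baseline}")
        return "\n".join(lines) + "\n"


def transcriptome_sizes(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    min_cells: int = 10,
) -> TranscriptomeSizeTable:
    """Mean per-cell total count per (sample, cell type) group.

    Groups with fewer than ``min_cells`` cells are omitted (logged): tiny
    groups make the group mean too noisy to anchor the linear fit.
    """
    if matrix.unit != "raw_count":
        raise ValueError(
            f"transcriptome sizes are defined on raw counts, got unit {matrix.unit!r}"
        )
    matrix, annotation = pair(matrix, annotation)
    sums = pd.Series(matrix.column_sums(), index=matrix.column_ids, name="size")
    ann = annotation.table.set_index("cell")
    df = ann.join(sums, how="inner")
    grouped = (
        df.groupby(["sample", "cell_type"])["size"]
        .agg(mean_size="mean", n_cells="size")
        .reset_index()
    )
    small = grouped[grouped["n_cells"] < min_cells]
    for _, row in small.iterrows():
        logger.info(
            "dropping group (%s, %s) with %d < %d cells",
            row["sample"], row["cell_type"], row["n_cells"], min_cells,
        )
    kept = grouped[grouped["n_cells"] >= min_cells]
    if kept.empty:
        raise ValueError(f"no (sample, cell_type) group has at least {min_cells} cells")
    return TranscriptomeSizeTable(kept)


def fit_clts(
    sizes: TranscriptomeSizeTable,
    baseline_sample: str | None = None,
    G: int = 0,
    *,
    weighted: bool = False,
) -> CltsModel:
    """Fit per-sample linear coefficients against the baseline sample.

    ``baseline_sample`` defaults to the first sample in lexicographic order.
    ``G`` is the gene count of the matrix the model will be applied to
    (stored for the per-gene shift).  With ``weighted=True`` the OLS is
    weighted by group cell counts.
    """
    samples = sizes.samples
    if baseline_sample is None:
        baseline_sample = samples[0]
    if baseline_sample not in samples:
        raise ValueError(f"baseline sample {baseline_sample!r} not in size table")
    wide = sizes.pivot()
    ncells = sizes.table.pivot(index="sample", columns="cell_type", values="n_cells")
    base = wide.loc[baseline_sample]
    coefficients: dict[str, tuple[float, float]] = {baseline_sample: (1.0, 0.0)}
    for s in samples:
        if s == baseline_sample:
            continue
        shared = wide.loc[s].notna() & base.notna()
        if shared.sum() < 2:
            raise ValueError(
                f"sample {s!r} shares fewer than 2 cell types with the baseline "
                f"{baseline_sample!r}; consider the merge advisory"
            )
        x = base[shared].to_numpy(float)
        y = wide.loc[s, shared].to_numpy(float)
        if weighted:
            w = np.sqrt(ncells.loc[s, shared].to_numpy(float))
            A = np.column_stack([x * w, w])
            coef, *_ = np.linalg.lstsq(A, y * w, rcond=None)
        else:
            A = np.column_stack([x, np.ones_like(x)])
            coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        a, b = float(coef[0]), float(coef[1])
        if a <= 0:
            raise ValueError(
                f"fitted slope a={a:.4g} for sample {s!r} is not positive; the "
                "proportional-amplification model does not hold (check annotation)"
            )
        coefficients[s] = (a, b)
    v_max = max(b / a for a, b in coefficients.values())
    return CltsModel(baseline_sample, coefficients, v_max, G)


def apply_clts(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    model: CltsModel,
) -> ExpressionMatrix:
    """Apply a fitted CLTS model to a raw count matrix.

    Each entry ``u`` of a cell from sample ``i`` becomes
    ``u/a_i + (v_max - b_i/a_i)/G``; values stay nonnegative because
    ``v_max >= b_i/a_i`` by construction.
    """
    if matrix.unit != "raw_count":
        raise ValueError(f"CLTS applies to raw counts, got unit {matrix.unit!r}")
    if model.G != matrix.n_genes:
        raise ValueError(
            f"model gene count G={model.G} does not match matrix ({matrix.n_genes} genes)"
        )
    matrix, annotation = pair(matrix, annotation)
    cell_sample = annotation.table.set_index("cell")["sample"]
    missing = sorted(set(cell_sample.unique()) - set(model.coefficients))
    if missing:
        raise ValueError(f"cells from samples absent from the CLTS model: {missing}")
    out = np.empty_like(matrix.values)
    col_samples = cell_sample.reindex(matrix.column_ids).to_numpy()
    for s, (a, b) in model.coefficients.items():
        cols = np.flatnonzero(col_samples == s)
        if cols.size == 0:
            continue
        shift = (model.v_max - b / a) / model.G
        out[:, cols] = matrix.values[:, cols] / a + shift
    return matrix.with_values(out, unit="CLTS")


def clts_normalize(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    baseline_sample: str | None = None,
    min_cells: int = 10,
) -> tuple[ExpressionMatrix, CltsModel]:
    """Fit and apply CLTS in one step.

    With a single sample CLTS is the identity on raw counts (the measured
    sizes already reflect biology); the returned model is (1, 0) / v_max 0.
    """
    matrix, annotation = pair(matrix, annotation)
    sizes = transcriptome_sizes(matrix, annotation, min_cells=min_cells)
    model = fit_clts(sizes, baseline_sample, G=matrix.n_genes)
    if len(model.coefficients) == 1:
        return matrix.with_values(matrix.values.copy(), unit="CLTS"), model
    return apply_clts(matrix, annotation, model), model


def merge_advisory(sizes: TranscriptomeSizeTable, threshold: float = 0.95) -> MergeAdvisory:
    """Report which samples could be merged before CLTS fitting.

    Samples whose shared-cell-type mean sizes correlate (Pearson r) at or
    above ``threshold`` with a candidate baseline are grouped with it;
    samples failing against every group (or sharing < 3 cell types with all
    others, where r is undefined) become singletons.
    """
    samples = sizes.samples
    if len(samples) < 2:
        raise ValueError("merge advisory requires at least 2 samples")
    wide = sizes.pivot()
    r = pd.DataFrame(np.nan, index=samples, columns=samples)
    for i, s in enumerate(samples):
        r.loc[s, s] = 1.0
        for t in samples[i + 1:]:
            shared = wide.loc[s].notna() & wide.loc[t].notna()
            if shared.sum() < 3:
                logger.warning(
                    "samples %r and %r share %d < 3 cell types; correlation undefined",
                    s, t, int(shared.sum()),
                )
                continue
            x = wide.loc[s, shared].to_numpy(float)
            y = wide.loc[t, shared].to_numpy(float)
            if np.std(x) == 0 or np.std(y) == 0:
                continue
            r.loc[s, t] = r.loc[t, s] = float(scipy.stats.pearsonr(x, y)[0])
    groups: list[list[str]] = []
    leaders: list[str] = []
    for s in samples:  # greedy, in sorted order: first fit group wins
        placed = False
        for leader, group in zip(leaders, groups):
            rv = r.loc[s, leader]
            if pd.notna(rv) and rv >= threshold:
                group.append(s)
                placed = True
                break
        if not placed:
            leaders.append(s)
            groups.append([s])
    largest = max(groups, key=len)
    return MergeAdvisory(
        threshold=threshold,
        pairwise_correlations=r,
        merge_groups=groups,
        suggested_baseline=largest[0],
    )


def merge_samples(annotation: CellAnnotation, groups: list[list[str]]) -> CellAnnotation:
    """Relabel sample IDs so each merge group becomes one sample (its first member)."""
    mapping = {s: g[0] for g in groups for s in g}
    t = annotation.table.copy()
    t["sample"] = t["sample"].map(lambda s: mapping.get(s, s))
    return CellAnnotation(t)


def scale_per_column(matrix: ExpressionMatrix, target_sum: float = 1e4) -> ExpressionMatrix:
    """Scale every column to sum to ``target_sum`` (1e4 -> CP10K, 1e6 -> CPM).

    This equalizes transcriptome sizes: appropriate within a cell type, but
    it destroys between-type size differences.
    """
    sums = matrix.column_sums()
    zero = np.flatnonzero(sums == 0)
    if zero.size:
        raise ValueError(
            f"all-zero columns cannot be scaled: {[matrix.column_ids[i] for i in zero[:10]]}"
        )
    unit = {1e4: "CP10K", 1e6: "CPM"}.get(float(target_sum), matrix.unit)
    if matrix.unit == "RPK" and float(target_sum) == 1e6:
        unit = "TPM"
    return matrix.with_values(matrix.values * (target_sum / sums), unit=unit)


def bulk_rpk(
    matrix: ExpressionMatrix,
    lengths: GeneLengthTable,
    *,
    length_unit_kb: bool = True,
    missing_length_policy: str = "error",
) -> ExpressionMatrix:
    """Divide each bulk gene's counts by its gene length (RPK).

    Gene-length normalization belongs on total bulk RNA-seq only: UMI-based
    single-cell counts are length-free, and applying RPK to both sides
    creates Type-II issues.
    """
    if matrix.unit not in {"raw_bulk", "raw_count"}:
        raise ValueError(f"RPK applies to raw bulk counts, got unit {matrix.unit!r}")
    L = lengths.get(matrix.gene_ids, policy=missing_length_policy)
    if missing_length_policy == "drop" and len(L) < matrix.n_genes:
        matrix = matrix.subset_genes(L.index.tolist())
    denom = L.to_numpy(float)
    if length_unit_kb:
        denom = denom / 1000.0
    return matrix.with_values(matrix.values / denom[:, None], unit="RPK")


def bulk_tpm(
    matrix: ExpressionMatrix,
    lengths: GeneLengthTable,
    **kwargs,
) -> ExpressionMatrix:
    """TPM = per-million column scaling of RPK."""
    return scale_per_column(bulk_rpk(matrix, lengths, **kwargs), 1e6)


def relative_difference(expr_a: pd.Series, expr_b: pd.Series) -> pd.Series:
    """Per-gene percent difference of b vs a: (b - a)/a * 100.

    Genes with ``expr_a == 0`` are excluded (division by zero) and logged.
    """
    a = expr_a.astype(float)
    b = expr_b.reindex(a.index).astype(float)
    zero = a.index[a == 0]
    if len(zero):
        logger.info("relative_difference: excluding %d genes with zero reference mean", len(zero))
    keep = a != 0
    return (b[keep] - a[keep]) / a[keep] * 100.0
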