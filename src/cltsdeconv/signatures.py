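"""Signature-gene selection: level-0/1/2 candidates, then stability ranking.

A gene is a *level-0* signature for a cell type when, against every other
cell type, (1) a two-sided t-test on its per-cell expression has p < 0.05
and (2) the mean fold change exceeds a threshold (default 2).  If exactly
one (two) other type(s) fail either test the gene is level-1 (level-2);
these are retained as fallbacks.  The final set per type is the top-k
candidates with the smallest coefficient of variation sigma/mu — the most
*stable* genes.  The rationale: for a single signature gene the implied
fraction estimate satisfies f_t/k_t ~ N(1, sigma^2/(mu^2 k_t)), so a small
sigma/mu gives a tight fraction estimate and mitigates Type-III issues.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.stats

from .io import CellAnnotation, ExpressionMatrix, pair

logger = logging.getLogger(__name__)

CANDIDATE_COLUMNS = ["gene_id", "cell_type", "level", "n_failed_comparisons", "mean", "sd", "cv"]


@dataclass
class SignatureSet:
    """Per-cell-type ordered signature gene lists (ascending cv), capped at k."""

    genes: dict[str, list[str]]
    k: int
    selection_mode: str  # "pairwise" or "one_vs_rest"
    candidates: pd.DataFrame = field(default=None, repr=False)  # selected rows, with rank

    @property
    def cell_types(self) -> list[str]:
        return sorted(self.genes)

    def union(self) -> list[str]:
        """All signature genes over all cell types, deduplicated, sorted."""
        return sorted({g for gs in self.genes.values() for g in gs})

    def to_frame(self) -> pd.DataFrame:
        return self.candidates

    def write(self, path) -> None:
        self.candidates.to_csv(path, sep="\t", index=False)


def _group_stats(matrix: ExpressionMatrix, annotation: CellAnnotation):
    """Per (gene, cell type) mean, ddof-1 variance and cell count; pooled across samples."""
    matrix, annotation = pair(matrix, annotation)
    types = annotation.cell_types
    by_cell = annotation.table.set_index("cell")["cell_type"]
    labels = by_cell.reindex(matrix.column_ids).to_numpy()
    means, variances, counts = {}, {}, {}
    for t in types:
        cols = np.flatnonzero(labels == t)
        if cols.size < 2:
            raise ValueError(f"cell type {t!r} has {cols.size} < 2 cells; variance undefined")
        sub = matrix.values[:, cols]
        means[t] = sub.mean(axis=1)
        variances[t] = sub.var(axis=1, ddof=1)
        counts[t] = cols.size
    return matrix, types, means, variances, counts


def _welch_p(m1, v1, n1, m2, v2, n2, equal_var=False):
    """Vectorized two-sided t-test p-values from group summary statistics."""
    with np.errstate(divide="ignore", invalid="ignore"):
        _, p = scipy.stats.ttest_ind_from_stats(
            m1, np.sqrt(v1), n1, m2, np.sqrt(v2), n2, equal_var=equal_var
        )
    # zero variance in both groups: identical constants -> p=1, else p=0
    both_const = (v1 == 0) & (v2 == 0)
    p = np.where(both_const, np.where(m1 == m2, 1.0, 0.0), p)
    return np.nan_to_num(p, nan=1.0)


def _fc_pass(mean_t, mean_o, fc_threshold):
    """Mean fold change mean_t/mean_o > threshold; other-mean 0 with own > 0 passes."""
    with np.errstate(divide="ignore", invalid="ignore"):
        fc = np.where(mean_o > 0, mean_t / np.where(mean_o > 0, mean_o, 1.0), np.inf)
    return (mean_t > 0) & (fc > fc_threshold)


def assign_levels(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    max_level: int = 2,
    *,
    equal_var: bool = False,
) -> pd.DataFrame:
    """Pairwise candidate search: for each (gene, cell type) count the other
    cell types failing the t-test or the fold-change test; keep genes with at
    most ``max_level`` failures.

    Returns a candidate table with columns ``CANDIDATE_COLUMNS``.  The
    t-test is Welch's (unequal variance) by default; ``equal_var=True``
    switches to Student's.  No multiple-testing correction is applied: each
    pairwise comparison is judged at raw p < ``p_threshold``.
    """
    matrix, types, means, variances, counts = _group_stats(matrix, annotation)
    if len(types) < 2:
        raise ValueError("candidate search requires at least 2 cell types")
    rows = []
    for t in types:
        failures = np.zeros(matrix.n_genes, dtype=int)
        for o in types:
            if o == t:
                continue
            p = _welch_p(means[t], variances[t], counts[t],
                         means[o], variances[o], counts[o], equal_var=equal_var)
            ok = (p < p_threshold) & _fc_pass(means[t], means[o], fc_threshold)
            failures += (~ok).astype(int)
        keep = (failures <= max_level) & (means[t] > 0)
        idx = np.flatnonzero(keep)
        sd = np.sqrt(variances[t][idx])
        mu = means[t][idx]
        rows.append(pd.DataFrame({
            "gene_id": [matrix.gene_ids[i] for i in idx],
            "cell_type": t,
            "level": failures[idx],
            "n_failed_comparisons": failures[idx],
            "mean": mu,
            "sd": sd,
            "cv": sd / mu,
        }))
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=CANDIDATE_COLUMNS)
    return out[CANDIDATE_COLUMNS]


def assign_levels_one_vs_rest(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    *,
    equal_var: bool = False,
) -> pd.DataFrame:
    """One-vs-rest candidate search (faster): one t-test and fold change of a
    type's cells against all other cells pooled; passing genes are level-0."""
    matrix, annotation = pair(matrix, annotation)
    types = annotation.cell_types
    if len(types) < 2:
        raise ValueError("candidate search requires at least 2 cell types")
    by_cell = annotation.table.set_index("cell")["cell_type"]
    labels = by_cell.reindex(matrix.column_ids).to_numpy()
    rows = []
    for t in types:
        cols = np.flatnonzero(labels == t)
        rest = np.flatnonzero(labels != t)
        if cols.size < 2 or rest.size < 2:
            raise ValueError(f"cell type {t!r} or its complement has < 2 cells")
        own, other = matrix.values[:, cols], matrix.values[:, rest]
        m1, v1 = own.mean(axis=1), own.var(axis=1, ddof=1)
        m2, v2 = other.mean(axis=1), other.var(axis=1, ddof=1)
        p = _welch_p(m1, v1, cols.size, m2, v2, rest.size, equal_var=equal_var)
        ok = (p < p_threshold) & _fc_pass(m1, m2, fc_threshold)
        idx = np.flatnonzero(ok)
        sd = np.sqrt(v1[idx])
        rows.append(pd.DataFrame({
            "gene_id": [matrix.gene_ids[i] for i in idx],
            "cell_type": t,
            "level": 0,
            "n_failed_comparisons": 0,
            "mean": m1[idx],
            "sd": sd,
            "cv": sd / m1[idx],
        }))
    out = pd.concat(rows, ignore_index=True) if rows else pd.DataFrame(columns=CANDIDATE_COLUMNS)
    return out[CANDIDATE_COLUMNS]


def select_stable(
    candidates: pd.DataFrame,
    k: int = 100,
    *,
    selection_mode: str = "pairwise",
) -> SignatureSet:
    """Per cell type, the k smallest-cv candidates, level-0 first.

    Level-0 candidates are taken first (cv ascending); if fewer than ``k``,
    level-1 then level-2 candidates are appended, each tier internally
    cv-sorted.  Ties on cv break by ascending gene_id for determinism.
    """
    if candidates.empty:
        raise ValueError("candidate table is empty")
    genes: dict[str, list[str]] = {}
    picked = []
    for t, sub in candidates.groupby("cell_type"):
        chosen = []
        n_chosen = 0
        for level in sorted(sub["level"].unique()):
            tier = sub[sub["level"] == level].sort_values(["cv", "gene_id"], kind="mergesort")
            need = k - n_chosen
            if need <= 0:
                break
            chosen.append(tier.head(need))
            n_chosen += min(need, len(tier))
        sel = pd.concat(chosen, ignore_index=True) if chosen else sub.head(0)
        if sel.empty:
            raise ValueError(f"cell type {t!r} has no signature candidates")
        if len(sel) < k:
            logger.info("cell type %r: only %d signature genes (< k=%d)", t, len(sel), k)
        sel = sel.copy()
        sel["rank"] = np.arange(1, len(sel) + 1)
        genes[str(t)] = sel["gene_id"].tolist()
        picked.append(sel)
    table = pd.concat(picked, ignore_index=True)
    return SignatureSet(genes=genes, k=k, selection_mode=selection_mode, candidates=table)


def find_signatures(
    matrix: ExpressionMatrix,
    annotation: CellAnnotation,
    fc_threshold: float = 2.0,
    p_threshold: float = 0.05,
    k: int = 100,
    mode: str = "pairwise",
) -> SignatureSet:
    """Candidate search + stability ranking in one call."""
    if mode == "pairwise":
        cand = assign_levels(matrix, annotation, fc_threshold, p_threshold)
    elif mode == "one_vs_rest":
        cand = assign_levels_one_vs_rest(matrix, annotation, fc_threshold, p_threshold)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return select_stable(cand, k=k, selection_mode=mode)
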