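"""Scoring deconvolution outputs and the Type-I/II/III issue-injection harness.

Issue taxonomy (fixed by the units the two inputs arrive in):

* **Type-I** — the single-cell reference was size-equalized (CP10K/CPM/TPM),
  erasing between-type transcriptome-size differences; deconvolution then
  overestimates large-transcriptome types.
* **Type-II** — the bulk side is raw total-RNA counts (length-proportional)
  while the reference is UMI-based (length-free); mismatched gene-length
  dependence biases the fractions.
* **Type-III** — a property of the fitting, not the inputs: ignoring
  per-gene, per-type expression variance when estimating fractions.  The
  package's own likelihood models variances; the mean-only least-squares
  baseline here is the Type-III-afflicted comparator.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.optimize
import scipy.stats

from .io import (
    SIZE_EQUALIZED_UNITS,
    CellAnnotation,
    ExpressionMatrix,
    GeneLengthTable,
    GroundTruthFractions,
    pair,
)
from .deconvolution import DeconvolutionOptions, DeconvolutionResults, deconvolve
from .normalization import scale_per_column
from .reference import ReferenceProfile, build_reference
from .signatures import SignatureSet, find_signatures
from .simulate import BulkSimScheme, simulate_bulk

logger = logging.getLogger(__name__)


@dataclass
class EvaluationReport:
    """Per-(mixture, cell type) prediction vs. truth with summaries."""

    table: pd.DataFrame = field(repr=False)  # mixture_id, cell_type, predicted, truth, relative_error
    per_type: pd.DataFrame = field(repr=False)  # cell_type, mean/sd of relative error
    pearson_r: float = np.nan
    per_mixture_r: pd.Series = field(default=None, repr=False)
    issue_flags: frozenset = frozenset()

    def summary(self) -> str:
        lines = [
            "Deconvolution evaluation",
            f"entries: {len(self.table)}   pooled Pearson r: "
            + ("undefined" if np.isnan(self.pearson_r) else f"{self.pearson_r:.4f}"),
            f"issue flags: {sorted(self.issue_flags) or 'none'}",
            "",
            "per-type relative error (%):",
            self.per_type.to_string(index=False, float_format=lambda v: f"{v:.2f}"),
        ]
        return "\n".join(lines) + "\n"


@dataclass
class DegComparison:
    """Differential-expression concordance between two normalizations."""

    table: pd.DataFrame = field(repr=False)
    pct_same_direction: float = np.nan
    n_significant_a: int = 0
    n_significant_b: int = 0
    n_significant_both: int = 0
    n_excluded: int = 0


def score_deconvolution(
    results: DeconvolutionResults | pd.DataFrame,
    truth: GroundTruthFractions,
    issue_flags: frozenset = frozenset(),
) -> EvaluationReport:
    """Relative error per (mixture, cell type) and pooled Pearson r.

    Relative error = (predicted - truth)/truth * 100, computed where truth
    > 0; zero-truth entries are kept with relative_error NaN and their
    absolute error in ``abs_error``.  The headline r pools all (mixture,
    type) pairs; a per-mixture r series is also reported.
    """
    pred = results.proportions if isinstance(results, DeconvolutionResults) else results
    true_wide = truth.pivot()
    missing_mix = set(pred.index) ^ set(true_wide.index)
    missing_type = set(pred.columns) ^ set(true_wide.columns)
    if missing_mix or missing_type:
        raise ValueError(
            f"prediction/truth key mismatch; orphan mixtures {sorted(missing_mix)[:5]}, "
            f"orphan cell types {sorted(missing_type)[:5]}"
        )
    true_wide = true_wide.loc[pred.index, pred.columns]
    long = pd.DataFrame({
        "mixture_id": np.repeat(pred.index, pred.shape[1]),
        "cell_type": np.tile(pred.columns, pred.shape[0]),
        "predicted": pred.to_numpy().ravel(),
        "truth": true_wide.to_numpy().ravel(),
    })
    with np.errstate(divide="ignore", invalid="ignore"):
        long["relative_error"] = np.where(
            long["truth"] > 0,
            (long["predicted"] - long["truth"]) / long["truth"] * 100.0,
            np.nan,
        )
    long["abs_error"] = long["predicted"] - long["truth"]
    per_type = (
        long.dropna(subset=["relative_error"])
        .groupby("cell_type")["relative_error"]
        .agg(mean_relative_error="mean", sd_relative_error="std")
        .reset_index()
    )
    x, y = long["truth"].to_numpy(), long["predicted"].to_numpy()
    if len(long) >= 2 and np.std(x) > 0 and np.std(y) > 0:
        pooled_r = float(scipy.stats.pearsonr(x, y)[0])
    else:
        pooled_r = np.nan  # degenerate (e.g. single mixture, constant truth)
    per_mix = {}
    for mid, sub in long.groupby("mixture_id"):
        xs, ys = sub["truth"].to_numpy(), sub["predicted"].to_numpy()
        per_mix[mid] = (
            float(scipy.stats.pearsonr(xs, ys)[0])
            if len(sub) >= 2 and np.std(xs) > 0 and np.std(ys) > 0 else np.nan
        )
    return EvaluationReport(
        table=long,
        per_type=per_type,
        pearson_r=pooled_r,
        per_mixture_r=pd.Series(per_mix),
        issue_flags=frozenset(issue_flags),
    )


def deg_concordance(
    matrix_a: ExpressionMatrix,
    matrix_b: ExpressionMatrix,
    annotation: CellAnnotation,
    type_pair: tuple[str, str],
    log2fc_threshold: float = 1.5,
    p_threshold: float = 0.05,
    *,
    fc_rule: str = "abs",
) -> DegComparison:
    """Compare differential expression between two normalizations of the
    same cells for one cell-type pair.

    Per gene and per normalization: log2 of the ratio of group means and a
    two-sided Wilcoxon rank-sum p-value; a gene is called significant when
    |log2FC| >= ``log2fc_threshold`` (``fc_rule="signed"`` uses log2FC >=
    threshold) and p < ``p_threshold``.  Genes with zero mean in both
    groups under a normalization are excluded and counted.
    """
    t1, t2 = type_pair
    if t1 == t2:
        raise ValueError("type_pair must name two distinct cell types")
    out = {}
    excluded_all = set()
    for name, mat in (("a", matrix_a), ("b", matrix_b)):
        m, ann = pair(mat, annotation)
        by_cell = ann.table.set_index("cell")["cell_type"]
        labels = by_cell.reindex(m.column_ids).to_numpy()
        g1 = m.values[:, labels == t1]
        g2 = m.values[:, labels == t2]
        if g1.shape[1] == 0 or g2.shape[1] == 0:
            raise ValueError(f"cell type {t1!r} or {t2!r} has no cells")
        m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
        dead = (m1 == 0) & (m2 == 0)
        excluded_all |= {m.gene_ids[i] for i in np.flatnonzero(dead)}
        with np.errstate(divide="ignore"):
            l2fc = np.log2(m1) - np.log2(m2)
        p = np.ones(m.n_genes)
        alive = np.flatnonzero(~dead)
        stat, pvals = scipy.stats.ranksums(g1[alive], g2[alive], axis=1)
        p[alive] = pvals
        out[name] = pd.DataFrame(
            {"log2fc": l2fc, "p": p, "dead": dead}, index=m.gene_ids
        )
    a, b = out["a"].align(out["b"], join="inner", axis=0)
    keep = ~(a["dead"] | b["dead"])
    a, b = a[keep], b[keep]
    if fc_rule == "abs":
        sig_a = (a["log2fc"].abs() >= log2fc_threshold) & (a["p"] < p_threshold)
        sig_b = (b["log2fc"].abs() >= log2fc_threshold) & (b["p"] < p_threshold)
    elif fc_rule == "signed":
        sig_a = (a["log2fc"] >= log2fc_threshold) & (a["p"] < p_threshold)
        sig_b = (b["log2fc"] >= log2fc_threshold) & (b["p"] < p_threshold)
    else:
        raise ValueError(f"unknown fc_rule {fc_rule!r}")
    finite = np.isfinite(a["log2fc"]) & np.isfinite(b["log2fc"])
    same_dir = np.sign(a.loc[finite, "log2fc"]) == np.sign(b.loc[finite, "log2fc"])
    table = pd.DataFrame({
        "gene_id": a.index,
        "log2fc_a": a["log2fc"].to_numpy(),
        "p_a": a["p"].to_numpy(),
        "significant_a": sig_a.to_numpy(),
        "log2fc_b": b["log2fc"].to_numpy(),
        "p_b": b["p"].to_numpy(),
        "significant_b": sig_b.to_numpy(),
    })
    return DegComparison(
        table=table,
        pct_same_direction=float(same_dir.mean() * 100.0) if finite.any() else np.nan,
        n_significant_a=int(sig_a.sum()),
        n_significant_b=int(sig_b.sum()),
        n_significant_both=int((sig_a & sig_b).sum()),
        n_excluded=len(excluded_all),
    )


def issue_matrix(reference_unit: str, bulk_unit: str) -> frozenset:
    """Which of the Type-I/II issues a (reference unit, bulk unit) pair incurs.

    Type-III is a property of the fitting model, not of the input units, so
    it never appears here: the package's own likelihood models variances.
    """
    ref_units = {"raw_count", "CLTS"} | SIZE_EQUALIZED_UNITS
    bulk_units = {"TPM", "RPK", "raw_bulk", "raw_count"}
    if reference_unit not in ref_units:
        raise ValueError(f"unrecognized reference unit {reference_unit!r}")
    if bulk_unit not in bulk_units:
        raise ValueError(f"unrecognized bulk unit {bulk_unit!r}")
    flags = set()
    if reference_unit in SIZE_EQUALIZED_UNITS:
        flags.add("I")
    if bulk_unit in {"raw_bulk", "raw_count"}:
        flags.add("II")
    return frozenset(flags)


def mean_only_nnls(bulk: ExpressionMatrix, reference: ReferenceProfile) -> pd.DataFrame:
    """Mean-only nonnegative least-squares baseline (Type-III afflicted).

    Fits x ~ mu f with f >= 0 and no variance weighting; returns a
    mixtures x cell-types proportion table.  Included solely as the
    comparator for issue-direction invariants, not a supported mode.
    """
    shared = [g for g in reference.gene_ids if g in set(bulk.gene_ids)]
    idx = pd.Index(reference.gene_ids).get_indexer(shared)
    mu = reference.mu[idx, :]
    sub = bulk.subset_genes(shared)
    rows = []
    for j in range(sub.n_columns):
        f, _ = scipy.optimize.nnls(mu, sub.values[:, j])
        total = f.sum()
        rows.append(f / total if total > 0 else np.full_like(f, np.nan))
    return pd.DataFrame(rows, index=sub.column_ids, columns=reference.cell_types)


def run_issue_experiment(
    scrna: ExpressionMatrix,
    annotation: CellAnnotation,
    lengths: GeneLengthTable,
    scheme: BulkSimScheme,
    combination: tuple[str, str],
    *,
    signatures: SignatureSet | None = None,
    options: DeconvolutionOptions | None = None,
) -> EvaluationReport:
    """End-to-end issue injection: simulate bulk, prepare both inputs in the
    requested units (guard rails overridden), deconvolve, score.

    ``combination`` is (reference_unit, bulk_unit), e.g. ("CP10K", "TPM")
    to inject Type-I issues only.
    """
    ref_unit, bulk_unit = combination
    flags = issue_matrix(ref_unit, bulk_unit)
    rpk, tpm, rawcount, truth = simulate_bulk(scrna, annotation, lengths, scheme)
    if signatures is None:
        signatures = find_signatures(scrna, annotation)
    if ref_unit in ("raw_count", "CLTS"):
        ref_matrix = scrna
    elif ref_unit == "CP10K":
        ref_matrix = scale_per_column(scrna, 1e4)
    elif ref_unit == "CPM":
        ref_matrix = scale_per_column(scrna, 1e6)
    else:
        raise ValueError(f"unsupported reference unit {ref_unit!r} for this harness")
    reference = build_reference(ref_matrix, annotation, signatures, allow_size_equalized=True)
    bulk = {"TPM": tpm, "RPK": rpk, "raw_bulk": rawcount, "raw_count": rawcount}[bulk_unit]
    res = deconvolve(bulk, reference, options, allow_raw_bulk=True)
    return score_deconvolution(res, truth, issue_flags=flags)
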