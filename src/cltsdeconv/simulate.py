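"""Synthetic scRNA-seq and pseudobulk generation.

The scRNA-seq generator emulates the structure the normalization and
deconvolution machinery assumes: cells of one type within a sample share a
mean transcriptome size; sizes differ multi-fold *between* types; and
technology-derived effects amplify every cell of a sample by a common
linear map (slope ``a_i``, offset ``b_i``).  Counts are negative binomial
per gene with a common dispersion; each type carries a block of boosted
marker genes; gene lengths are uniform integers.

Pseudobulk mixtures sum the raw counts of sampled cells — UMI counts are
length-free, so the summed profile plays the role of RPK; TPM is its
per-million scaling and a length-proportional "raw count" bulk is RPK
times gene length.  Ground-truth fractions are the *realized* sampled-cell
fractions, not the requested scheme values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    CellAnnotation,
    ExpressionMatrix,
    GeneLengthTable,
    GroundTruthFractions,
)
from .normalization import scale_per_column

logger = logging.getLogger(__name__)

#: Marker enrichment factor: markers are this many fold higher in their own
#: type than the shared baseline profile, large enough to clear the
#: fold-change threshold even against a type with an 8-fold larger
#: transcriptome.
MARKER_BOOST = 30.0

#: Default per-type mean transcriptome sizes (UMI per cell), spanning 8-fold
#: as observed between e.g. neurons and astrocytes.
DEFAULT_TYPE_SIZES = (40_000.0, 25_000.0, 15_000.0, 10_000.0, 7_000.0, 5_000.0)


@dataclass
class ScrnaSimConfig:
    """Configuration for the scRNA-seq generator."""

    n_genes: int = 2000
    n_cell_types: int = 6
    cells_per_type_per_sample: int = 300
    n_samples: int = 1
    type_mean_transcriptome_sizes: tuple[float, ...] = DEFAULT_TYPE_SIZES
    sample_amplification: tuple[float, ...] = (1.0,)
    sample_offset: tuple[float, ...] = (0.0,)
    marker_fraction: float = 0.3
    nb_dispersion: float = 10.0  # NB size parameter theta; var = mu + mu^2/theta
    gene_length_range: tuple[int, int] = (500, 10_000)
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.type_mean_transcriptome_sizes) != self.n_cell_types:
            raise ValueError("need one mean transcriptome size per cell type")
        if len(self.sample_amplification) != self.n_samples:
            raise ValueError("need one amplification factor per sample")
        if len(self.sample_offset) != self.n_samples:
            raise ValueError("need one offset per sample")
        if min(self.type_mean_transcriptome_sizes) <= 0:
            raise ValueError("transcriptome sizes must be positive")
        if min(self.sample_amplification) <= 0:
            raise ValueError("amplification factors must be positive")
        if not 0 < self.marker_fraction < 1:
            raise ValueError("marker_fraction must be in (0, 1)")
        if int(self.marker_fraction * self.n_genes) < self.n_cell_types:
            raise ValueError("too few marker genes for the number of cell types")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")


@dataclass
class BulkSimScheme:
    """How mixture cell counts are chosen.

    scheme="equal": equal cell counts for every type in every mixture.
    scheme="fixed_random": one random fraction vector shared by all mixtures.
    scheme="per_sample_random": fresh random fractions per mixture.
    """

    scheme: str = "equal"
    n_mixtures: int = 100
    cells_per_mixture: int = 1000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.scheme not in {"equal", "fixed_random", "per_sample_random"}:
            raise ValueError(f"unknown scheme {self.scheme!r}")
        if self.n_mixtures < 1:
            raise ValueError("n_mixtures must be >= 1")
        if self.cells_per_mixture < 1:
            raise ValueError("cells_per_mixture must be >= 1")


def _type_mean_profiles(config: ScrnaSimConfig, rng: np.random.Generator) -> np.ndarray:
    """Per-type expected expression per cell, genes x types; column sums equal
    the configured mean transcriptome sizes."""
    G, T = config.n_genes, config.n_cell_types
    base = rng.lognormal(mean=0.0, sigma=1.0, size=G)
    n_markers = int(config.marker_fraction * G)
    marker_genes = rng.choice(G, size=n_markers, replace=False)
    owner = np.repeat(np.arange(T), int(np.ceil(n_markers / T)))[:n_markers]
    profiles = np.tile(base[:, None], (1, T))
    profiles[marker_genes, :] = base[marker_genes, None] / MARKER_BOOST
    profiles[marker_genes, owner] = base[marker_genes]
    # renormalize each type so the expected per-cell sum hits its target size
    sizes = np.asarray(config.type_mean_transcriptome_sizes, dtype=float)
    profiles *= sizes / profiles.sum(axis=0)
    return profiles


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, theta: float) -> np.ndarray:
    """Negative-binomial counts with mean ``mean`` and size ``theta``."""
    mean = np.asarray(mean, dtype=float)
    p = theta / (theta + mean)
    out = np.zeros(mean.shape, dtype=np.int64)
    pos = mean > 0
    out[pos] = rng.negative_binomial(theta, p[pos])
    return out


def simulate_scrna(
    config: ScrnaSimConfig,
) -> tuple[ExpressionMatrix, CellAnnotation, GeneLengthTable]:
    """Generate a raw-count scRNA-seq matrix, annotation and gene lengths.

    Sample ``i`` amplifies the expected per-cell transcriptome size of type
    ``t`` to ``a_i * size_t + b_i``, planting the exact linear relation the
    CLTS fit estimates.
    """
    rng = np.random.default_rng(config.seed)
    profile_rng = np.random.default_rng(rng.integers(2**31))
    count_rng = np.random.default_rng(rng.integers(2**31))
    length_rng = np.random.default_rng(rng.integers(2**31))

    profiles = _type_mean_profiles(config, profile_rng)
    sizes = np.asarray(config.type_mean_transcriptome_sizes, dtype=float)
    gene_ids = [f"gene_{g:05d}" for g in range(config.n_genes)]

    blocks, cells, samples, types = [], [], [], []
    for i in range(config.n_samples):
        a, b = config.sample_amplification[i], config.sample_offset[i]
        for t in range(config.n_cell_types):
            target = a * sizes[t] + b
            if target <= 0:
                raise ValueError(f"sample {i} amplification drives type {t} size nonpositive")
            mean = profiles[:, t] * (target / sizes[t])
            n = config.cells_per_type_per_sample
            block = _nb_draw(count_rng, np.tile(mean[:, None], (1, n)), config.nb_dispersion)
            blocks.append(block)
            for c in range(n):
                cells.append(f"s{i}_t{t}_c{c:04d}")
                samples.append(f"sample_{i}")
                types.append(f"type_{t}")
    values = np.concatenate(blocks, axis=1).astype(float)
    matrix = ExpressionMatrix(values, gene_ids, cells, unit="raw_count")
    annotation = CellAnnotation(pd.DataFrame({"cell": cells, "sample": samples, "cell_type": types}))
    lo, hi = config.gene_length_range
    lengths = GeneLengthTable(pd.Series(
        length_rng.integers(lo, hi + 1, size=config.n_genes),
        index=pd.Index(gene_ids, name="gene_id"), name="length",
    ))
    return matrix, annotation, lengths


def random_fractions(n_types: int, seed: int) -> np.ndarray:
    """Uniform-on-the-simplex (symmetric Dirichlet(1)) fraction vector."""
    if n_types < 2:
        raise ValueError("need at least 2 cell types")
    return np.random.default_rng(seed).dirichlet(np.ones(n_types))


def _counts_from_fractions(fractions: np.ndarray, total: int) -> np.ndarray:
    """Integer cell counts approximating fractions; sums to ``total``,
    largest-remainder rounding."""
    raw = fractions * total
    counts = np.floor(raw).astype(int)
    short = total - counts.sum()
    order = np.argsort(-(raw - counts), kind="stable")
    counts[order[:short]] += 1
    return counts


def simulate_bulk(
    scrna: ExpressionMatrix,
    annotation: CellAnnotation,
    lengths: GeneLengthTable,
    scheme: BulkSimScheme,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix, GroundTruthFractions]:
    """Build pseudobulk mixtures from one sample's raw counts.

    Returns (rpk, tpm, rawcount, truth).  Cells are sampled without
    replacement; if a type's demand exceeds its supply the draw for that
    type falls back to with-replacement (logged).
    """
    if scrna.unit != "raw_count":
        raise ValueError(
            f"pseudobulk must be generated from raw counts, got {scrna.unit!r}; "
            "size-equalized units hide the very structure under study"
        )
    if len(annotation.samples) != 1:
        raise ValueError(
            "pseudobulk cells must come from a single sample (transcriptome sizes "
            f"of one type vary across samples); got samples {annotation.samples}"
        )
    types = annotation.cell_types
    by_type = {
        t: annotation.table.loc[annotation.table["cell_type"] == t, "cell"].tolist()
        for t in types
    }
    rng = np.random.default_rng(scheme.seed)
    frac_rng = np.random.default_rng(rng.integers(2**31))
    cell_rng = np.random.default_rng(rng.integers(2**31))

    n = len(types)
    if scheme.scheme == "equal":
        per_mixture_fracs = [np.full(n, 1.0 / n)] * scheme.n_mixtures
    elif scheme.scheme == "fixed_random":
        shared = frac_rng.dirichlet(np.ones(n))
        per_mixture_fracs = [shared] * scheme.n_mixtures
    else:  # per_sample_random
        per_mixture_fracs = [frac_rng.dirichlet(np.ones(n)) for _ in range(scheme.n_mixtures)]

    col_index = pd.Index(scrna.column_ids)
    cols = []
    truth_rows = []
    mixture_ids = [f"mixture_{j:03d}" for j in range(scheme.n_mixtures)]
    for j, fracs in enumerate(per_mixture_fracs):
        counts = _counts_from_fractions(fracs, scheme.cells_per_mixture)
        chosen: list[str] = []
        for t, k in zip(types, counts):
            pool = by_type[t]
            if k == 0:
                continue
            if not pool:
                raise ValueError(f"scheme demands cells of type {t!r} but none are annotated")
            replace = k > len(pool)
            if replace:
                logger.info("mixture %d: type %r demand %d exceeds supply %d; "
                            "sampling with replacement", j, t, k, len(pool))
            chosen.extend(cell_rng.choice(pool, size=k, replace=replace))
        idx = col_index.get_indexer(chosen)
        cols.append(scrna.values[:, idx].sum(axis=1))
        realized = counts / counts.sum()
        for t, fr in zip(types, realized):
            truth_rows.append((mixture_ids[j], t, fr))

    rpk = ExpressionMatrix(np.column_stack(cols), list(scrna.gene_ids), mixture_ids, unit="RPK")
    tpm = scale_per_column(rpk, 1e6)
    L = lengths.get(rpk.gene_ids).to_numpy(float)
    rawcount = rpk.with_values(rpk.values * L[:, None], unit="raw_bulk")
    truth = GroundTruthFractions(pd.DataFrame(truth_rows, columns=["mixture_id", "cell_type", "fraction"]))
    return rpk, tpm, rawcount, truth
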