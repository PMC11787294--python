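# Methods

This note documents the models, the numerical choices, and what the
synthetic benchmarks do and do not demonstrate.

## CLTS normalization

**Model.** Cells of one type within a sample share a mean measured
transcriptome size; technology-derived effects (capture efficiency,
depth) act approximately linearly on all cells of a sample.  For sample
*i* and cell type *j*, let `x_ij` be the mean of per-cell total counts.
Fixing a baseline sample (default: first in lexicographic order,
overridable), we fit per sample

    x_ij = a_i · x_1j + b_i        over cell types shared with the baseline,

by ordinary least squares (a cell-count-weighted variant is available via
`weighted=True`; the estimator is otherwise deliberately minimal).  With
`v_max = max_i b_i / a_i`, every entry `u` of a cell in sample *i* becomes

    u / a_i + (v_max − b_i/a_i) / G,

`G` the gene count.  The per-gene shift distributes the intercept
correction uniformly over genes and guarantees nonnegative output because
`v_max ≥ b_i/a_i` by construction.  After the transform, a shared cell
type has mean size `x_1j + v_max` in every sample (exactly so when the
linear relation holds exactly; up to OLS residuals otherwise), while
between-type differences survive untouched.  With a single sample the
transform is the identity: measured sizes already reflect biology.

**Assumptions and failure modes.** The fit needs ≥ 2 cell types shared
with the baseline (error otherwise) and a positive slope — `a_i ≤ 0`
indicates mis-annotation or a broken amplification model and is a hard
error, not a clamp.  Groups with fewer than `min_cells` (default 10)
cells are excluded from the size table because tiny groups make `x_ij`
too noisy to anchor the fit; `v_max` is consequently maximized over the
samples that survive this filter.  When cross-sample correlations of
cell-type sizes are weak, the merge advisory reports pairwise Pearson r
(threshold 0.95 by default), proposes merge groups and a baseline; merged
samples are implemented by relabeling sample IDs before fitting.
Correlations over fewer than three shared types are reported as
undefined and the sample is kept as a singleton.

## Signature genes

Candidates are scored per (gene, cell type) against every other type with
a two-sided Welch t-test (p < 0.05) and the ratio of group means
(> 2-fold; a comparison with other-type mean 0 and own mean > 0 counts as
passing).  Zero failures → level-0, one → level-1, two → level-2; other
genes are dropped.  Welch rather than Student because between-type
variances are routinely unequal; a pooled-variance flag exists.  No
multiple-testing correction is applied by default — each pairwise
comparison is judged at its raw p-value — since the selection is a
screening step whose output is re-ranked, not an inference procedure.
The one-vs-rest mode pools all other types into one comparison group and
emits level-0 only; it is faster and coarser.

The final set takes, per type, the k (default 100) candidates with the
smallest σ/μ, filling from level-0 first, then level-1, then level-2,
each tier cv-sorted, ties broken by gene ID for determinism.  The σ/μ
ranking is justified by the single-gene estimator: if
`f_t μ_it` estimates the summed expression of `k_t` cells, then
`f_t/k_t ~ N(1, σ²_it/(μ²_it k_t))`, so low-cv genes pin the fraction
tighter.  Candidate statistics are pooled across samples (computed on
CLTS-normalized data for multi-sample inputs), matching how the reference
is built.

## Reference profile

Per signature gene and cell type, the mean and unbiased (ddof = 1)
variance over all cells of the type, pooled across samples.  Inputs must
be raw counts (single sample) or CLTS; CP10K/CPM/TPM references are
rejected because size equalization is precisely what produces Type-I
biases — the override exists only for the issue-injection harness.
Variances below `1e-12·μ²` are floored at that value before likelihood
evaluation to avoid zero-variance singularities; genes with no variance
mass in any type are dropped from the fit and counted.

## Deconvolution likelihood

For a mixture with `k_t` cells of type *t*, the bulk expression of gene
*i* is a sum of per-cell draws; by the CLT it is approximately
`N(Σ_t k_t μ_it, Σ_t k_t σ²_it)`.  With measured bulk `x_i = c·g_i` and
`f_t = c·k_t`, the joint density over the m signature genes is

    L(f) = Π_i (2π c v_i)^(−1/2) exp(−(x_i − m_i)² / (2 c v_i)),
    m_i = Σ_t f_t μ_it,   v_i = Σ_t f_t σ²_it.

`f ≥ 0` is estimated by maximizing `log L`.  Two nuisance scales are
profiled in closed form at every evaluation:

* `c`: stationarity gives `c* = (1/m) Σ_i (x_i − m_i)²/v_i`, floored at
  1e-12 when residuals vanish.  `c` never affects the proportions; a
  `fixed_one` mode (c ≡ 1) is retained for sensitivity analysis.  Note
  the printed variance term is `c·Σ f_t σ²` (not `c²`), consistent with
  the derivation through `f_t = c k_t`; the implementation follows it
  literally.
* the overall scale `s` of `f` along a direction `w` (`f = s·w`): the
  means are linear in `s`, so the optimal `s` is the weighted
  least-squares solve `s* = Σ(x M/V)/Σ(M²/V)` with `M = μw`, `V = σ²w`.
  Profiling `s` makes the working objective a function of the mixture
  *direction* only, which in turn makes the estimated proportions exactly
  invariant to rescaling the bulk column.

The outer optimization is bound-constrained L-BFGS-B (f ≥ 0, numerical
gradients, ftol 1e-8 relative, ≤ 1000 iterations) with multi-start:
uniform proportions plus seeded Dirichlet(1) draws (5 restarts by
default).  The best restart is refined by a few rounds of iteratively
reweighted nonnegative least squares — near the optimum the residual
term dominates the profiled objective, exactly so for noiseless mixtures
where quasi-Newton line searches stall on the vanishing-residual kink —
and the refinement is kept only when it improves the objective.
Signature genes absent from the bulk are dropped (count reported; a type
losing > 50 % of its signatures warns); a type with no positive reference
mean left in the bulk gene set is an error.  Proportions are reported on
the full simplex; no "unknown" component is modeled.

Unit guard rails encode the issue taxonomy: the reference must be
raw-count/CLTS, the bulk TPM or RPK.  Raw bulk counts raise a Type-II
error unless `allow_raw_bulk=True`; size-equalized references raise a
Type-I error unless `allow_size_equalized=True`.  Both overrides exist so
the evaluation harness can inject the issues deliberately.

## Synthetic data

The generator emulates the structure the method assumes, no more: a
shared lognormal(0, 1) baseline expression profile; per type, a block of
marker genes (30 % of genes split evenly across types) boosted 30-fold —
markers are near-exclusive in real atlases, and the boost must clear the
2-fold threshold against a type with an 8-fold larger transcriptome;
profiles rescaled so the expected per-cell sum equals the configured type
size; negative-binomial counts with dispersion θ = 10 (variance
μ + μ²/θ); uniform integer gene lengths on [500, 10000].  Sample effects
scale the expected per-cell size of type *t* in sample *i* to
`a_i·size_t + b_i`, planting the exact linear relation the CLTS fit
estimates (implemented as mean scaling rather than post-hoc thinning,
which could not realize `a_i > 1` or offsets).  All randomness flows from
one seed through named substreams.

Default study conditions: 6 types, 300 cells/type, 2000 genes, sizes
(40k, 25k, 15k, 10k, 7k, 5k) — an 8-fold span typical of
neuron-vs-glia comparisons.  Pseudobulk mixtures (default 1000 cells,
100 mixtures) sample cells without replacement (with replacement only
when demand exceeds supply, logged), sum raw counts (length-free UMI
sums play the role of RPK), scale per-million for TPM, and multiply by
gene length for a length-proportional "raw count" bulk.  Ground truth
records realized sampled-cell fractions (largest-remainder rounding of
the requested fractions), not the requested values.  Mixture fractions
are symmetric Dirichlet(1) — uniform on the simplex — where a law is
needed.

**What the generator does not emulate**: ambient RNA, doublets,
dropout beyond NB noise, batch structure within a sample, gene-gene
correlation, or mismatch between reference and mixture populations.
Passing benchmarks therefore demonstrate correctness of the estimation
machinery under the model's own assumptions (and the predicted failure
modes under injected Type-I/II issues); they do not certify accuracy on
real tissue, where reference-mixture mismatch (Type-III in its hard
form) dominates.

## Evaluation

Relative error is `(predicted − truth)/truth × 100`, computed where truth
is positive; zero-truth entries are reported as absolute errors (the
synthetic schemes never produce exact zeros, so this is an extension
policy).  The headline correlation pools all (mixture, type) pairs, in
the style of predicted-vs-truth scatter plots; per-mixture r is also
reported, and degenerate cases (constant truth) yield NaN rather than 0.
DEG concordance compares log2 mean ratios and two-sided Wilcoxon
rank-sum calls (|log2FC| ≥ 1.5, p < 0.05 by default; the threshold rule
is switchable to signed) between two normalizations of the same cells.
A mean-only NNLS baseline is included solely as the Type-III-afflicted
comparator for direction-invariance checks.

## Problem sizes and determinism

The shipped benchmarks run the full study conditions (2000 genes, 1800
cells, 100 mixtures of 1000 cells, 5 optimizer restarts) in tens of
seconds on one CPU; the unit suites use smaller instances of the same
generators.  Every stochastic component takes an explicit seed and the
end-to-end pipeline is byte-reproducible under a fixed seed.
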