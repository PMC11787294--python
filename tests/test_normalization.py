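import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cltsdeconv as cd
from cltsdeconv.normalization import TranscriptomeSizeTable


def sizes_table(rows):
    return TranscriptomeSizeTable(pd.DataFrame(
        rows, columns=["sample", "cell_type", "mean_size", "n_cells"]))


def make_cells(sample, cell_type, sums, n_genes=4, prefix=""):
    """Deterministic cells whose column sums are exactly ``sums``."""
    cols = []
    ids = []
    for i, s in enumerate(sums):
        v = np.zeros(n_genes)
        v[0] = s
        cols.append(v)
        ids.append(f"{prefix}{sample}_{cell_type}_{i}")
    return np.column_stack(cols), ids, [sample] * len(sums), [cell_type] * len(sums)


def assemble(parts):
    vals, cells, samples, types = [], [], [], []
    for v, i, s, t in parts:
        vals.append(v)
        cells += i
        samples += s
        types += t
    m = cd.ExpressionMatrix(np.column_stack(vals), [f"g{k}" for k in range(vals[0].shape[0])], cells)
    ann = cd.CellAnnotation(pd.DataFrame({"cell": cells, "sample": samples, "cell_type": types}))
    return m, ann


class TestTranscriptomeSizes:
    def test_mean_of_column_sums(self):
        m, ann = assemble([make_cells("s1", "A", [10, 20])])
        t = cd.transcriptome_sizes(m, ann, min_cells=2).table
        assert t["mean_size"].iloc[0] == 15
        assert t["n_cells"].iloc[0] == 2

    def test_all_zero_cell_contributes_zero(self):
        m, ann = assemble([make_cells("s1", "A", [10, 20, 0])])
        t = cd.transcriptome_sizes(m, ann, min_cells=2).table
        assert t["mean_size"].iloc[0] == 10

    def test_two_samples_three_types_hand_sums(self):
        # hand-computed means: s1 A (5+7)/2=6, s1 B (2+4)/2=3, s1 C (9+1)/2=5
        #                      s2 A (8+10)/2=9, s2 B (6+2)/2=4, s2 C (3+3)/2=3
        parts = [
            make_cells("s1", "A", [5, 7]), make_cells("s1", "B", [2, 4]),
            make_cells("s1", "C", [9, 1]), make_cells("s2", "A", [8, 10]),
            make_cells("s2", "B", [6, 2]), make_cells("s2", "C", [3, 3]),
        ]
        m, ann = assemble(parts)
        wide = cd.transcriptome_sizes(m, ann, min_cells=2).pivot()
        expected = pd.DataFrame(
            [[6.0, 3.0, 5.0], [9.0, 4.0, 3.0]],
            index=pd.Index(["s1", "s2"], name="sample"),
            columns=pd.Index(["A", "B", "C"], name="cell_type"))
        pd.testing.assert_frame_equal(wide, expected, check_dtype=False)

    def test_min_cells_filter_and_empty_error(self):
        m, ann = assemble([make_cells("s1", "A", [10, 20]), make_cells("s1", "B", [5])])
        t = cd.transcriptome_sizes(m, ann, min_cells=2).table
        assert t["cell_type"].tolist() == ["A"]
        with pytest.raises(ValueError, match="at least 5"):
            cd.transcriptome_sizes(m, ann, min_cells=5)


class TestFitClts:
    def test_single_sample_identity(self):
        model = cd.fit_clts(sizes_table([("s1", "A", 100.0, 10), ("s1", "B", 50.0, 10)]), G=10)
        assert model.coefficients == {"s1": (1.0, 0.0)}
        assert model.v_max == 0.0

    def test_exact_proportional(self):
        rows = [("s1", t, x, 10) for t, x in zip("ABCD", [10, 20, 30, 40])]
        rows += [("s2", t, 1.5 * x, 10) for t, x in zip("ABCD", [10, 20, 30, 40])]
        model = cd.fit_clts(sizes_table(rows), G=10)
        a, b = model.coefficients["s2"]
        assert a == pytest.approx(1.5, abs=1e-12)
        assert b == pytest.approx(0.0, abs=1e-9)
        assert model.v_max == pytest.approx(0.0, abs=1e-10)

    def test_affine_closed_form(self):
        # y = 2x + 1000 exactly over 5 shared types -> OLS recovers it exactly
        xs = [1000.0, 2000.0, 3000.0, 5000.0, 8000.0]
        rows = [("s1", f"t{i}", x, 10) for i, x in enumerate(xs)]
        rows += [("s2", f"t{i}", 2 * x + 1000, 10) for i, x in enumerate(xs)]
        model = cd.fit_clts(sizes_table(rows), G=100)
        a, b = model.coefficients["s2"]
        assert a == pytest.approx(2.0, rel=1e-10)
        assert b == pytest.approx(1000.0, rel=1e-9)
        assert model.v_max == pytest.approx(500.0, rel=1e-9)

    def test_too_few_shared_types(self):
        rows = [("s1", "A", 10.0, 10), ("s1", "B", 20.0, 10), ("s2", "A", 15.0, 10)]
        with pytest.raises(ValueError, match="merge advisory"):
            cd.fit_clts(sizes_table(rows))

    def test_negative_slope_rejected(self):
        rows = [("s1", t, x, 10) for t, x in zip("ABC", [10.0, 20.0, 30.0])]
        rows += [("s2", t, x, 10) for t, x in zip("ABC", [30.0, 20.0, 10.0])]
        with pytest.raises(ValueError, match="not positive"):
            cd.fit_clts(sizes_table(rows))


class TestApplyClts:
    def test_baseline_unchanged_when_vmax_zero(self, tiny):
        m, ann = tiny
        model = cd.CltsModel("s1", {"s1": (1.0, 0.0)}, 0.0, m.n_genes)
        out = cd.apply_clts(m, ann, model)
        np.testing.assert_array_equal(out.values, m.values)
        assert out.unit == "CLTS"

    def test_formula_by_hand(self):
        # a=2, b=0, v_max=0: entry 10 -> 5
        m = cd.ExpressionMatrix(np.array([[10.0]]), ["g1"], ["c1"])
        ann = cd.CellAnnotation(pd.DataFrame(
            {"cell": ["c1"], "sample": ["s2"], "cell_type": ["A"]}))
        model = cd.CltsModel("s1", {"s1": (1.0, 0.0), "s2": (2.0, 0.0)}, 0.0, 1)
        out = cd.apply_clts(m, ann, model)
        assert out.values[0, 0] == 5.0

    def test_per_gene_shift(self):
        # a=2, b=1000, v_max=500, G=100: entry 0 stays 0 for the v_max sample;
        # a sample with b/a = 100 gets per-gene shift (500-100)/100 = 4
        G = 100
        vals = np.zeros((G, 2))
        m = cd.ExpressionMatrix(vals, [f"g{i}" for i in range(G)], ["c1", "c2"])
        ann = cd.CellAnnotation(pd.DataFrame({
            "cell": ["c1", "c2"], "sample": ["s2", "s3"], "cell_type": ["A", "A"]}))
        model = cd.CltsModel(
            "s1", {"s1": (1.0, 0.0), "s2": (2.0, 1000.0), "s3": (1.0, 100.0)}, 500.0, G)
        out = cd.apply_clts(m, ann, model)
        np.testing.assert_allclose(out.values[:, 0], 0.0)
        np.testing.assert_allclose(out.values[:, 1], 4.0)

    def test_unknown_sample_rejected(self, tiny):
        m, ann = tiny
        model = cd.CltsModel("s9", {"s9": (1.0, 0.0)}, 0.0, m.n_genes)
        with pytest.raises(ValueError, match="s1"):
            cd.apply_clts(m, ann, model)

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000))
    def test_nonnegativity_property(self, seed):
        """CLTS never produces negatives for any valid model."""
        rng = np.random.default_rng(seed)
        G = rng.integers(2, 12)
        n = rng.integers(2, 8)
        vals = rng.integers(0, 30, size=(G, n)).astype(float)
        samples = [f"s{rng.integers(0, 3)}" for _ in range(n)]
        m = cd.ExpressionMatrix(vals, [f"g{i}" for i in range(G)], [f"c{j}" for j in range(n)])
        ann = cd.CellAnnotation(pd.DataFrame({
            "cell": m.column_ids, "sample": samples, "cell_type": ["A"] * n}))
        coeffs = {"s0": (1.0, 0.0)}
        for s in set(samples) - {"s0"}:
            coeffs[s] = (float(rng.uniform(0.2, 3.0)), float(rng.uniform(-500, 500)))
        v_max = max(b / a for a, b in coeffs.values())
        model = cd.CltsModel("s0", coeffs, v_max, G)
        out = cd.apply_clts(m, ann, model)
        assert (out.values >= 0).all()


def test_clts_equalizes_exactly_linear_sizes():
    """On noiseless data whose per-sample sizes follow x_ij = a_i x_1j + b_i
    exactly, the CLTS-transformed mean sizes agree across samples to 1e-9."""
    base = np.array([4000.0, 8000.0, 16000.0, 32000.0])
    plans = {"s0": (1.0, 0.0), "s1": (1.5, 500.0), "s2": (0.8, -200.0)}
    G = 5
    parts = []
    for s, (a, b) in plans.items():
        for j, x in enumerate(base):
            target = a * x + b
            v, i, ss, tt = _exact_cells(s, f"T{j}", target, G)
            parts.append((v, i, ss, tt))
    vals = np.column_stack([p[0] for p in parts])
    cells = sum((p[1] for p in parts), [])
    samples = sum((p[2] for p in parts), [])
    types = sum((p[3] for p in parts), [])
    m = cd.ExpressionMatrix(vals, [f"g{k}" for k in range(G)], cells)
    ann = cd.CellAnnotation(pd.DataFrame({"cell": cells, "sample": samples, "cell_type": types}))
    normalized, model = cd.clts_normalize(m, ann, min_cells=2)
    assert normalized.unit == "CLTS"
    assert (normalized.values >= 0).all()
    sums = pd.Series(normalized.values.sum(axis=0), index=normalized.column_ids)
    df = ann.table.set_index("cell").join(sums.rename("size"))
    wide = df.groupby(["sample", "cell_type"])["size"].mean().unstack()
    expected = base + model.v_max
    for s in plans:
        np.testing.assert_allclose(wide.loc[s].to_numpy(), expected, atol=1e-9 * base.max())


def _exact_cells(sample, cell_type, total, G):
    v = np.zeros((G, 2))
    v[0, :] = total
    ids = [f"{sample}_{cell_type}_{i}" for i in range(2)]
    return v, ids, [sample] * 2, [cell_type] * 2


def test_single_sample_clts_is_identity(small_world):
    _, matrix, annotation, _ = small_world
    normalized, model = cd.clts_normalize(matrix, annotation)
    np.testing.assert_array_equal(normalized.values, matrix.values)
    assert normalized.unit == "CLTS"
    assert model.v_max == 0.0


class TestMergeAdvisory:
    def test_proportional_samples_one_group(self):
        rows = [("s1", t, x, 10) for t, x in zip("ABC", [10.0, 20.0, 30.0])]
        rows += [("s2", t, 2 * x, 10) for t, x in zip("ABC", [10.0, 20.0, 30.0])]
        adv = cd.merge_advisory(sizes_table(rows))
        assert adv.merge_groups == [["s1", "s2"]]
        assert adv.pairwise_correlations.loc["s1", "s2"] == pytest.approx(1.0)

    def test_anticorrelated_samples_split(self):
        rows = [("s1", t, x, 10) for t, x in zip("ABC", [10.0, 20.0, 30.0])]
        rows += [("s2", t, x, 10) for t, x in zip("ABC", [30.0, 20.0, 10.0])]
        adv = cd.merge_advisory(sizes_table(rows))
        assert adv.merge_groups == [["s1"], ["s2"]]

    def test_three_samples_constructed_correlations(self):
        # hand Pearson r: s2 = s1 + small bump -> r ~ 0.999; s3 scrambled -> low
        s1 = [10.0, 20.0, 30.0, 40.0]
        s2 = [11.0, 20.0, 31.0, 40.0]
        s3 = [30.0, 10.0, 40.0, 15.0]
        def r(x, y):
            x, y = np.asarray(x), np.asarray(y)
            xc, yc = x - x.mean(), y - y.mean()
            return float((xc * yc).sum() / np.sqrt((xc**2).sum() * (yc**2).sum()))
        assert r(s1, s2) > 0.99 and r(s1, s3) < 0.95
        rows = [(s, f"t{j}", v, 10) for s, vec in [("s1", s1), ("s2", s2), ("s3", s3)]
                for j, v in enumerate(vec)]
        adv = cd.merge_advisory(sizes_table(rows), threshold=0.95)
        assert adv.merge_groups == [["s1", "s2"], ["s3"]]
        assert adv.pairwise_correlations.loc["s1", "s2"] == pytest.approx(r(s1, s2))
        assert adv.suggested_baseline == "s1"
        assert "Extra" not in adv.to_text()  # plain report, no stray headers

    def test_insufficient_shared_types_singleton(self):
        rows = [("s1", "A", 10.0, 10), ("s1", "B", 20.0, 10),
                ("s2", "A", 10.0, 10), ("s2", "B", 20.0, 10)]
        adv = cd.merge_advisory(sizes_table(rows))
        assert adv.merge_groups == [["s1"], ["s2"]]  # r undefined on 2 points


class TestScalePerColumn:
    def test_hand_example(self):
        m = cd.ExpressionMatrix(np.array([[1.0], [1.0], [2.0]]), ["g1", "g2", "g3"], ["c1"])
        out = cd.scale_per_column(m, 1e4)
        np.testing.assert_allclose(out.values[:, 0], [2500, 2500, 5000])
        assert out.unit == "CP10K"

    def test_idempotent_and_permutation_invariant(self):
        rng = np.random.default_rng(3)
        m = cd.ExpressionMatrix(rng.uniform(0.1, 5, (6, 4)),
                                [f"g{i}" for i in range(6)], list("abcd"))
        once = cd.scale_per_column(m, 1e4)
        twice = cd.scale_per_column(once, 1e4)
        np.testing.assert_allclose(once.values, twice.values, atol=1e-9)
        perm = ["c", "a", "d", "b"]
        np.testing.assert_allclose(
            cd.scale_per_column(m.subset_columns(perm), 1e4).values,
            once.subset_columns(perm).values, atol=1e-9)

    def test_column_sums_hit_target(self):
        rng = np.random.default_rng(4)
        m = cd.ExpressionMatrix(rng.uniform(0, 9, (10, 5)),
                                [f"g{i}" for i in range(10)], [f"c{j}" for j in range(5)])
        out = cd.scale_per_column(m, 1e6)
        np.testing.assert_allclose(out.column_sums(), 1e6, rtol=1e-9)
        assert out.unit == "CPM"

    def test_zero_column_rejected(self):
        m = cd.ExpressionMatrix(np.array([[1.0, 0.0]]), ["g1"], ["c1", "c2"])
        with pytest.raises(ValueError, match="c2"):
            cd.scale_per_column(m, 1e4)


class TestBulkLengthNormalization:
    def test_rpk_hand_example(self):
        m = cd.ExpressionMatrix(np.array([[100.0]]), ["g1"], ["b1"], unit="raw_bulk")
        lengths = cd.GeneLengthTable(pd.Series([2000.0], index=["g1"]))
        out = cd.bulk_rpk(m, lengths)
        assert out.values[0, 0] == 50.0
        assert out.unit == "RPK"

    def test_uniform_lengths_proportional(self):
        vals = np.array([[10.0], [30.0]])
        m = cd.ExpressionMatrix(vals, ["g1", "g2"], ["b1"], unit="raw_bulk")
        lengths = cd.GeneLengthTable(pd.Series([1000.0, 1000.0], index=["g1", "g2"]))
        out = cd.bulk_rpk(m, lengths)
        np.testing.assert_allclose(out.values / vals, 1.0)

    def test_tpm_algebraic_round_trip(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(1, 200, size=(8, 3)).astype(float)
        L = pd.Series(rng.integers(500, 5000, 8).astype(float),
                      index=[f"g{i}" for i in range(8)])
        m = cd.ExpressionMatrix(counts, L.index.tolist(), ["b1", "b2", "b3"], unit="raw_bulk")
        tpm = cd.bulk_tpm(m, cd.GeneLengthTable(L))
        assert tpm.unit == "TPM"
        np.testing.assert_allclose(tpm.column_sums(), 1e6, rtol=1e-9)
        # multiply back by lengths, rescale per column: proportional to counts
        back = tpm.values * L.to_numpy()[:, None]
        back = back / back.sum(axis=0) * counts.sum(axis=0)
        np.testing.assert_allclose(back, counts, rtol=1e-9)


class TestRelativeDifference:
    @pytest.mark.parametrize("a, b, expected", [(10.0, 15.0, 50.0), (4.0, 4.0, 0.0), (4.0, 1.0, -75.0)])
    def test_hand_values(self, a, b, expected):
        out = cd.relative_difference(pd.Series({"g": a}), pd.Series({"g": b}))
        assert out["g"] == pytest.approx(expected)

    def test_zero_reference_excluded(self):
        out = cd.relative_difference(pd.Series({"g1": 0.0, "g2": 2.0}),
                                     pd.Series({"g1": 5.0, "g2": 3.0}))
        assert out.index.tolist() == ["g2"]
        assert out["g2"] == pytest.approx(50.0)
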