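"""Expression preprocessing: filtering, size factors, VST, batch removal."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from vdsignalflow import (
    CountMatrix, ExpressionMatrix, IdMap,
    filter_low_counts, size_factors, vst, remove_batch, map_ids,
    condition_means, ddct_relative_expression,
)


def _cm(rows, genes=None, samples=None, conditions=None, batches=None):
    arr = np.asarray(rows)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    meta = pd.DataFrame({
        "condition": conditions or ["c"] * arr.shape[1],
        "batch": batches or ["A"] * arr.shape[1]}, index=samples)
    return CountMatrix(counts=pd.DataFrame(arr, index=genes, columns=samples),
                       meta=meta)


class TestFilterLowCounts:
    def test_worked_example_keeps_only_all_high_gene(self):
        m = _cm([[5, 5], [4, 10], [0, 0]])
        out = filter_low_counts(m, min_count=5)
        assert out.genes == ["g0"]
        assert out.samples == m.samples

    def test_min_count_zero_is_identity(self):
        m = _cm([[5, 5], [4, 10], [0, 0]])
        out = filter_low_counts(m, min_count=0)
        assert out.genes == m.genes

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(42)
        rows = rng.negative_binomial(2, 0.2, size=(100, 6))
        m = _cm(rows)
        out = filter_low_counts(m, min_count=5)
        expected = [f"g{i}" for i, row in enumerate(rows)
                    if all(int(x) >= 5 for x in row)]
        assert out.genes == expected

    def test_empty_result_warns_not_raises(self):
        m = _cm([[1, 1], [2, 2]])
        with pytest.warns(UserWarning, match="all genes removed"):
            out = filter_low_counts(m, min_count=5)
        assert out.genes == []


class TestSizeFactors:
    def test_identical_columns_give_unit_factors(self):
        m = _cm([[10, 10], [7, 7]])
        f = size_factors(m)
        assert np.allclose(f, [1.0, 1.0])

    def test_hand_computed_example(self):
        # geomeans: sqrt(200)=14.142, sqrt(1800)=42.426; ratio medians 1/sqrt2, sqrt2
        m = _cm([[10, 20], [30, 60]])
        f = size_factors(m)
        assert abs(f.iloc[0] - 1 / np.sqrt(2)) < 1e-12
        assert abs(f.iloc[1] - np.sqrt(2)) < 1e-12

    def test_column_scaling_scales_its_factor(self):
        rng = np.random.default_rng(0)
        rows = rng.integers(10, 200, size=(50, 4))
        f0 = size_factors(_cm(rows))
        scaled = rows.astype(float).copy()
        scaled[:, 2] *= 3
        f1 = size_factors(_cm(scaled.astype(int)))
        ratio = (f1 / f0).to_numpy()
        assert np.allclose(ratio[2] / ratio[0], 3.0, rtol=1e-9)

    def test_no_reference_genes_raises(self):
        m = _cm([[0, 5], [5, 0]])
        with pytest.raises(ValueError, match="no reference genes"):
            size_factors(m)


class TestVst:
    @pytest.mark.parametrize("count,factor,expected", [
        (0, 1.0, 0.0),                         # log2(1)
        (7, 1.0, 3.0),                         # log2(8)
        (30, np.sqrt(2), np.log2(30 / np.sqrt(2) + 1)),  # ~4.4646
    ])
    def test_hand_values(self, count, factor, expected):
        m = _cm([[count]])
        e = vst(m, np.array([factor]))
        assert abs(e.values.iloc[0, 0] - expected) < 1e-10

    def test_reference_value_against_hand_calculation(self):
        # 30 / sqrt(2) + 1 = 22.2132...; log2 of that is 4.47335
        m = _cm([[30]])
        e = vst(m, np.array([np.sqrt(2)]))
        assert abs(e.values.iloc[0, 0] - 4.47335) < 5e-5

    def test_nonpositive_factor_raises(self):
        with pytest.raises(ValueError, match="positive"):
            vst(_cm([[1]]), np.array([0.0]))

    @given(st.lists(st.integers(0, 10_000), min_size=2, max_size=8,
                    unique=True))
    def test_strictly_monotone_in_count(self, counts):
        counts = sorted(counts)
        m = _cm([[c] for c in counts])
        e = vst(m, np.array([1.7]))
        vals = e.values.to_numpy().ravel()
        assert (np.diff(vals) > 0).all()

    def test_pipeline_invariant_to_gene_order(self):
        rng = np.random.default_rng(3)
        rows = rng.integers(5, 300, size=(30, 4))
        m = _cm(rows)
        perm = rng.permutation(30)
        mp = _cm(rows[perm], genes=[f"g{i}" for i in perm])
        e = vst(filter_low_counts(m), size_factors(filter_low_counts(m)))
        ep = vst(filter_low_counts(mp), size_factors(filter_low_counts(mp)))
        joined = ep.values.loc[e.values.index]
        assert np.allclose(e.values.to_numpy(), joined.to_numpy())


class TestRemoveBatch:
    def _expr(self, values, conditions, batches):
        samples = [f"s{j}" for j in range(values.shape[1])]
        meta = pd.DataFrame({"condition": conditions, "batch": batches},
                            index=samples)
        df = pd.DataFrame(values, index=[f"g{i}" for i in range(len(values))],
                          columns=samples)
        return ExpressionMatrix(values=df, meta=meta)

    def test_single_batch_is_identity(self):
        e = self._expr(np.arange(8.0).reshape(2, 4),
                       ["a", "a", "b", "b"], ["A"] * 4)
        out = remove_batch(e)
        assert np.allclose(out.values, e.values)

    def test_exact_linear_construction(self):
        """value = 1*conditionB + 2*batchB exactly; removal zeroes the batch
        coefficient and leaves the condition coefficient at 1."""
        cond = np.array([0, 0, 1, 1, 0, 0, 1, 1], dtype=float)
        batch = np.array([0, 1, 0, 1, 0, 1, 0, 1], dtype=float)
        values = (1.0 * cond + 2.0 * batch)[None, :]
        e = self._expr(values, ["a" if c == 0 else "b" for c in cond],
                       ["A" if b == 0 else "B" for b in batch])
        out = remove_batch(e)
        X = np.column_stack([np.ones(8), cond, batch])
        beta, *_ = np.linalg.lstsq(X, out.values.to_numpy().ravel(),
                                   rcond=None)
        assert abs(beta[2]) < 1e-8     # batch gone
        assert abs(beta[1] - 1.0) < 1e-8  # condition preserved

    def test_simulated_batch_coefficients_center_on_zero(self):
        rng = np.random.default_rng(5)
        n_genes, n = 200, 20
        cond = np.repeat([0, 1], n // 2).astype(float)
        batch = np.tile([0, 1], n // 2).astype(float)
        values = (rng.normal(0, 0.1, size=(n_genes, n))
                  + 2.0 * batch + 0.5 * cond)
        e = self._expr(values, ["a" if c == 0 else "b" for c in cond],
                       ["A" if b == 0 else "B" for b in batch])
        out = remove_batch(e)
        X = np.column_stack([np.ones(n), cond, batch])
        beta, *_ = np.linalg.lstsq(X, out.values.to_numpy().T, rcond=None)
        assert np.mean(np.abs(beta[2])) < 0.05

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        values = rng.normal(size=(20, 8))
        e = self._expr(values, ["a", "b"] * 4, ["A"] * 4 + ["B"] * 4)
        once = remove_batch(e)
        twice = remove_batch(once)
        assert np.allclose(once.values, twice.values, atol=1e-10)

    def test_confounded_design_raises(self):
        e = self._expr(np.ones((2, 4)), ["a", "a", "b", "b"],
                       ["A", "A", "B", "B"])
        with pytest.raises(ValueError, match="confounded|collinear"):
            remove_batch(e)


class TestMapIds:
    def _expr(self, genes):
        df = pd.DataFrame(np.arange(len(genes) * 2.0).reshape(len(genes), 2),
                          index=genes, columns=["s0", "s1"])
        meta = pd.DataFrame({"condition": ["c", "c"], "batch": ["A", "A"]},
                            index=["s0", "s1"])
        return ExpressionMatrix(values=df, meta=meta)

    def test_noninjective_map_rejected(self):
        with pytest.raises(ValueError, match="colliding targets.*A"):
            IdMap(pairs={"a": "A", "b": "A"})

    def test_partial_map_keeps_original_order(self):
        e = self._expr(["a", "b", "c", "d", "e"])
        idmap = IdMap(pairs={"a": "A", "c": "C", "e": "E"})
        out = map_ids(e, idmap)
        assert out.genes == ["A", "C", "E"]

    def test_empty_map_warns_and_empties(self):
        e = self._expr(["a", "b"])
        with pytest.warns(UserWarning, match="no genes"):
            out = map_ids(e, IdMap(pairs={}))
        assert out.genes == []

    def test_on_unmapped_error(self):
        e = self._expr(["a", "b"])
        with pytest.raises(ValueError, match="unmapped"):
            map_ids(e, IdMap(pairs={"a": "A"}), on_unmapped="error")


class TestConditionMeans:
    def test_two_values_average(self):
        df = pd.DataFrame([[1.0, 3.0]], index=["g"], columns=["s0", "s1"])
        meta = pd.DataFrame({"condition": ["c", "c"], "batch": ["A", "A"]},
                            index=["s0", "s1"])
        e = ExpressionMatrix(values=df, meta=meta)
        w = condition_means(e, condition="c")
        assert w["g"] == 2.0

    def test_matches_masked_row_mean_oracle(self):
        rng = np.random.default_rng(8)
        values = rng.normal(size=(10, 6))
        samples = [f"s{j}" for j in range(6)]
        conds = ["x", "y", "x", "y", "x", "y"]
        meta = pd.DataFrame({"condition": conds, "batch": ["A"] * 6},
                            index=samples)
        e = ExpressionMatrix(values=pd.DataFrame(
            values, index=[f"g{i}" for i in range(10)], columns=samples),
            meta=meta)
        w = condition_means(e, condition="y")
        mask = np.array([c == "y" for c in conds])
        for i in range(10):
            assert abs(w[f"g{i}"] - values[i, mask].mean()) < 1e-12

    def test_unknown_condition_raises(self):
        df = pd.DataFrame([[1.0]], index=["g"], columns=["s0"])
        meta = pd.DataFrame({"condition": ["c"], "batch": ["A"]},
                            index=["s0"])
        with pytest.raises(ValueError, match="unknown condition"):
            condition_means(ExpressionMatrix(values=df, meta=meta),
                            condition="nope")


@pytest.mark.parametrize("cts,expected", [
    ((20.0, 20.0, 20.0, 20.0), 1.0),   # ddCt = 0
    ((24.0, 20.0, 25.0, 20.0), 2.0),   # ddCt = -1
    ((25.0, 20.0, 27.0, 20.0), 4.0),   # 2^-(5-7)
])
def test_ddct_relative_expression(cts, expected):
    assert ddct_relative_expression(*cts) == pytest.approx(expected)


def test_ddct_rejects_nonfinite():
    with pytest.raises(ValueError):
        ddct_relative_expression(np.nan, 1.0, 1.0, 1.0)
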