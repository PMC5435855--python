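"""The six normalization methods and their replicate-based evaluation."""

import numpy as np
import pandas as pd
import pytest

from srna_dekit.core import ConfigurationError, ExpressionMatrix, SampleHierarchy
from srna_dekit.normalization import (
    evaluate_normalizations,
    normalize,
    normalize_deseq,
    normalize_quantile_adapted,
    normalize_subsampling,
    normalize_tmm,
    normalize_total_count,
    normalize_upper_quartile,
)


def _seq(i: int) -> str:
    """Deterministic unique 21-mer for row i."""
    return "".join("ACGT"[(i >> (2 * k)) & 3] for k in range(8)) + "A" * 13


def matrix_from(cols: dict, treatments=None) -> ExpressionMatrix:
    n = len(next(iter(cols.values())))
    seqs = [_seq(i) for i in range(n)]
    if treatments is None:
        treatments = [("t", list(cols))]
    return ExpressionMatrix(
        pd.DataFrame(cols, index=seqs, dtype=float), SampleHierarchy(treatments)
    )


class TestTotalCount:
    def test_worked_example(self):
        m = matrix_from({"a": [10, 30], "b": [10, 30]})
        res = normalize_total_count(m, 1e6)
        assert res.matrix.values["a"].tolist() == [250000.0, 750000.0]

    def test_identity_when_total_equals_colsum(self):
        m = matrix_from({"a": [10, 30]})
        res = normalize_total_count(m, 40)
        np.testing.assert_allclose(res.matrix.values["a"], [10, 30])

    def test_scaling_below_depth_shrinks_everything(self):
        # scaling at 1 M for a 10 M library reduces every expression level x0.1
        m = matrix_from({"a": [4_000_000, 6_000_000]})
        res = normalize_total_count(m, 1_000_000)
        np.testing.assert_allclose(res.matrix.values["a"], [400_000, 600_000])

    def test_column_sums_equal_total(self, rng):
        cols = {f"r{i}": rng.integers(0, 500, 60) for i in range(4)}
        m = matrix_from(cols)
        res = normalize_total_count(m, "average")
        T = float(m.column_sums().mean())
        np.testing.assert_allclose(res.matrix.column_sums(), T, rtol=1e-6)

    def test_zero_column_rejected(self):
        m = matrix_from({"a": [0, 0], "b": [1, 2]})
        with pytest.raises(ConfigurationError, match="a"):
            normalize_total_count(m)


class TestUpperQuartile:
    def test_type7_quartile_of_nonzero(self):
        m = matrix_from({"a": [1, 2, 3, 4, 0], "b": [1, 2, 3, 4, 0]})
        res = normalize_upper_quartile(m)
        assert res.scale_factors["a"] * (1 + 2 + 3 + 4) / (1 + 2 + 3 + 4)  # factors exist
        # UQ of (1,2,3,4) under linear interpolation is 3.25; T = mean of UQs = 3.25
        np.testing.assert_allclose(res.matrix.values["a"], [1, 2, 3, 4, 0])

    def test_doubled_column_equalized(self):
        m = matrix_from({"a": [1, 2, 3, 4], "b": [2, 4, 6, 8]})
        res = normalize_upper_quartile(m)
        np.testing.assert_allclose(res.matrix.values["a"], res.matrix.values["b"])

    def test_too_few_nonzero_rejected(self):
        m = matrix_from({"a": [1, 2, 0, 0], "b": [1, 2, 3, 4]})
        with pytest.raises(ConfigurationError):
            normalize_upper_quartile(m)


class TestTMM:
    def test_identical_columns_unit_factors(self, rng):
        col = rng.integers(1, 400, 80)
        m = matrix_from({"a": col, "b": col.copy()})
        res = normalize_tmm(m)
        assert res.scale_factors["a"] == pytest.approx(res.scale_factors["b"], abs=1e-9)

    def test_depth_multiple_columns_equalized(self, rng):
        col = rng.integers(1, 400, 80).astype(float)
        m = matrix_from({"a": col, "b": 2 * col})
        res = normalize_tmm(m)
        np.testing.assert_allclose(
            res.matrix.values["a"], res.matrix.values["b"], rtol=1e-6
        )

    def test_trimming_robust_to_outliers(self, rng):
        """Extreme one-sided outliers in 5% of sequences barely perturb the
        normalized between-column ratio of the remaining sequences (they fall
        in the trimmed M tail); an untrimmed mean would be dragged off."""
        col = rng.integers(10, 400, 200).astype(float)
        spiked_b = 2 * col.copy()
        spiked_b[:10] *= 100  # 5% extreme outlier sequences in one column
        spiked = matrix_from({"a": col, "b": spiked_b})
        out = normalize_tmm(spiked).matrix.values
        ratio = (out["b"].to_numpy()[10:] / out["a"].to_numpy()[10:])
        assert abs(np.median(ratio) - 1) < 0.01


class TestDeseq:
    def test_identical_columns_unit_factors(self, rng):
        col = rng.integers(1, 400, 50)
        m = matrix_from({"a": col, "b": col.copy()})
        res = normalize_deseq(m)
        np.testing.assert_allclose(list(res.scale_factors.values()), 1.0)

    def test_doubled_column_sqrt2_factors(self):
        m = matrix_from({"a": [1, 2, 4], "b": [2, 4, 8]})
        res = normalize_deseq(m)
        assert res.scale_factors["a"] == pytest.approx(1 / np.sqrt(2))
        assert res.scale_factors["b"] == pytest.approx(np.sqrt(2))
        np.testing.assert_allclose(res.matrix.values["a"], res.matrix.values["b"])

    def test_no_common_nonzero_sequence_rejected(self):
        m = matrix_from({"a": [1, 0], "b": [0, 1]})
        with pytest.raises(ConfigurationError, match="filter"):
            normalize_deseq(m)


class TestQuantileAdapted:
    def test_rank_wise_means(self):
        m = matrix_from({"a": [2, 4], "b": [4, 8]})
        res = normalize_quantile_adapted(m)
        assert res.matrix.values["a"].tolist() == [3.0, 6.0]
        assert res.matrix.values["b"].tolist() == [3.0, 6.0]

    def test_tie_rule_averages_reference_values(self):
        # reference distribution (3, 3.5, 9.5) from the two sorted columns
        m = matrix_from({"a": [5, 5, 10], "b": [1, 2, 9]})
        res = normalize_quantile_adapted(m)
        assert res.matrix.values["a"].tolist() == [3.25, 3.25, 9.5]
        assert res.matrix.values["b"].tolist() == [3.0, 3.5, 9.5]

    def test_zeros_stay_exactly_zero(self):
        m = matrix_from({"a": [0, 4], "b": [2, 6]})
        res = normalize_quantile_adapted(m)
        assert res.matrix.values.loc[res.matrix.sequences[0], "a"] == 0.0

    def test_equal_multisets_without_ties_or_zeros(self, rng):
        cols = {f"r{i}": rng.permutation(rng.choice(np.arange(1, 10_000), 40, replace=False))
                for i in range(3)}
        res = normalize_quantile_adapted(matrix_from(cols))
        vals = res.matrix.values
        ref = sorted(vals["r0"])
        for c in vals.columns:
            assert sorted(vals[c]) == pytest.approx(ref)

    def test_idempotent_on_tie_free_zero_free(self, rng):
        cols = {f"r{i}": rng.choice(np.arange(1, 10_000), 30, replace=False) for i in range(3)}
        once = normalize_quantile_adapted(matrix_from(cols)).matrix
        twice = normalize_quantile_adapted(once).matrix
        pd.testing.assert_frame_equal(once.values, twice.values)


class TestSubsampling:
    @pytest.fixture
    def counts_matrix(self, rng):
        return matrix_from({
            "a": rng.integers(0, 30, 100),
            "b": rng.integers(0, 60, 100),
        })

    def test_sums_equal_min_column_sum(self, counts_matrix):
        res = normalize_subsampling(counts_matrix, seed=5, n_boot=20)
        target = int(counts_matrix.column_sums().min())
        assert res.matrix.column_sums().tolist() == [target, target]

    def test_without_replacement_bound(self, counts_matrix):
        res = normalize_subsampling(counts_matrix, seed=5, n_boot=20)
        assert (res.matrix.values.to_numpy() <= counts_matrix.values.to_numpy()).all()
        # zeros preserved: nothing can be drawn from an absent sequence
        assert (res.matrix.values.to_numpy()[counts_matrix.values.to_numpy() == 0] == 0).all()

    def test_seed_reproducibility(self, counts_matrix):
        r1 = normalize_subsampling(counts_matrix, seed=7, n_boot=10)
        r2 = normalize_subsampling(counts_matrix, seed=7, n_boot=10)
        r3 = normalize_subsampling(counts_matrix, seed=8, n_boot=10)
        pd.testing.assert_frame_equal(r1.matrix.values, r2.matrix.values)
        target = int(counts_matrix.column_sums().min())
        assert r3.matrix.column_sums().tolist() == [target, target]


@pytest.mark.parametrize("method", ["rpt", "uq", "tmm", "deseq", "quantile", "subsample"])
def test_zeros_and_nonnegativity_preserved(method, rng):
    cols = {f"r{i}": np.concatenate([rng.integers(1, 300, 50), np.zeros(10, int)])
            for i in range(3)}
    for c in cols.values():
        rng.shuffle(c)
    # guarantee a shared nonzero row for the median-of-ratios method
    for c in cols.values():
        c[0] = max(c[0], 1)
    m = matrix_from(cols)
    res = normalize(m, method, seed=3, **({"n_boot": 10} if method == "subsample" else {}))
    out = res.matrix.values.to_numpy()
    assert (out >= 0).all()
    assert (out[m.values.to_numpy() == 0] == 0).all()


class TestEvaluation:
    def test_total_count_centers_doubled_replicate(self, rng):
        col = rng.integers(1, 400, 60)
        m = matrix_from({"r1": col, "r2": 2 * col}, treatments=[("t", ["r1", "r2"])])
        evaluation, ranking, _ = evaluate_normalizations(m, ["rpt"])
        raw = ranking.set_index("method").loc["raw", "centering_score"]
        rpt = ranking.set_index("method").loc["rpt", "centering_score"]
        assert raw == pytest.approx(1.0)   # log2(2) before normalization
        assert rpt == pytest.approx(0.0, abs=1e-9)

    def test_identical_matrices_tie_in_ranking(self, rng):
        col = rng.integers(1, 400, 60)
        m = matrix_from({"r1": col, "r2": col + rng.integers(0, 3, 60)},
                        treatments=[("t", ["r1", "r2"])])
        _, ranking, results = evaluate_normalizations(m, ["rpt", "deseq"])
        # both methods rescale without changing between-replicate ratios much;
        # scores are finite and the table includes every method plus raw
        assert set(ranking.method) == {"raw", "rpt", "deseq"}

    def test_needs_replicated_treatment(self, rng):
        m = matrix_from({"r1": rng.integers(1, 10, 5), "r2": rng.integers(1, 10, 5)},
                        treatments=[("t1", ["r1"]), ("t2", ["r2"])])
        with pytest.raises(ConfigurationError):
            evaluate_normalizations(m, ["rpt"])
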