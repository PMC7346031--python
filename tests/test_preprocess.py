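"""Normalization, filtering and batch-correction contracts."""

import numpy as np
import pandas as pd
import pytest

from glycochol import (
    ClinicalRecord,
    ExpressionMatrix,
    PreprocessConfig,
    batch_correct,
    filter_by_purity,
    log2fc_screen,
    log_transform,
    tpm_normalize,
)


def counts_matrix(arr, genes=None, samples=None):
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"G{i}" for i in range(arr.shape[0])]
    samples = samples or [f"S{j}" for j in range(arr.shape[1])]
    return ExpressionMatrix(
        pd.DataFrame(arr, index=genes, columns=samples), scale_tag="counts"
    )


class TestTpm:
    def test_equal_lengths_proportional_split(self):
        m = counts_matrix([[1], [1], [2]])
        tpm = tpm_normalize(m, {"G0": 1000, "G1": 1000, "G2": 1000})
        assert np.allclose(
            tpm.values.to_numpy().ravel(), [250_000, 250_000, 500_000]
        )

    def test_length_normalization(self):
        # counts (10, 20, 70) with lengths (1, 2, 7) kb -> equal rates
        m = counts_matrix([[10], [20], [70]])
        tpm = tpm_normalize(m, {"G0": 1000, "G1": 2000, "G2": 7000})
        assert np.allclose(tpm.values.to_numpy().ravel(), [1e6 / 3] * 3)

    def test_all_zero_sample_rejected(self):
        m = counts_matrix([[0, 1], [0, 2]])
        with pytest.raises(ValueError, match="zero total rate"):
            tpm_normalize(m, {"G0": 1000, "G1": 1000})

    def test_missing_length_rejected(self):
        m = counts_matrix([[1], [1]])
        with pytest.raises(ValueError, match="missing gene lengths"):
            tpm_normalize(m, {"G0": 1000})

    def test_columns_sum_to_million(self, rng):
        m = counts_matrix(rng.uniform(0.1, 100, size=(30, 8)))
        lengths = {f"G{i}": rng.integers(500, 5000) for i in range(30)}
        tpm = tpm_normalize(m, lengths)
        assert np.allclose(tpm.values.sum(axis=0), 1e6, rtol=1e-6)

    def test_requires_counts_scale(self):
        m = counts_matrix([[1.0]])
        tpm = tpm_normalize(m, {"G0": 1000})
        with pytest.raises(ValueError, match="counts"):
            tpm_normalize(tpm, {"G0": 1000})


class TestLogTransform:
    def test_known_values_and_monotonicity(self, rng):
        m = ExpressionMatrix(
            pd.DataFrame([[0.0, 999.0]], index=["G0"], columns=["A", "B"]),
            scale_tag="tpm",
        )
        out = log_transform(m)
        assert out.values.loc["G0", "A"] == 0.0
        assert out.values.loc["G0", "B"] == pytest.approx(3.0)
        x = np.sort(rng.uniform(0, 1e5, size=50))
        m2 = ExpressionMatrix(
            pd.DataFrame(x[None, :], index=["G0"], columns=[f"S{i}" for i in range(50)]),
            scale_tag="tpm",
        )
        y = log_transform(m2).values.to_numpy().ravel()
        assert np.all(np.diff(y) > 0)


def _clinical(purities):
    return [
        ClinicalRecord(f"S{j}", 10.0, 1, "A", purity=p)
        for j, p in enumerate(purities)
    ]


class TestPurityFilter:
    def test_strict_below_threshold_excluded(self):
        m = counts_matrix(np.ones((2, 3)))
        _, kept, excluded = filter_by_purity(m, _clinical([0.29, 0.30, 0.8]))
        assert excluded == ["S0"]
        assert [r.sample_id for r in kept] == ["S1", "S2"]

    def test_all_pass_is_identity_and_idempotent(self):
        m = counts_matrix(np.arange(6.0).reshape(2, 3))
        out, kept, excluded = filter_by_purity(m, _clinical([0.5, 0.6, 0.7]))
        assert excluded == []
        assert out.values.equals(m.values)
        out2, _, excluded2 = filter_by_purity(out, _clinical([0.5, 0.6, 0.7]))
        assert excluded2 == []
        assert out2.values.equals(out.values)

    def test_sample_missing_from_clinical_rejected(self):
        m = counts_matrix(np.ones((1, 2)))
        with pytest.raises(ValueError, match="missing from clinical"):
            filter_by_purity(m, _clinical([0.5]))

    def test_missing_purity_needs_permissive_flag(self):
        m = counts_matrix(np.ones((1, 1)))
        clin = [ClinicalRecord("S0", 1.0, 1, "A", purity=None)]
        with pytest.raises(ValueError, match="purity"):
            filter_by_purity(m, clin)
        with pytest.warns(UserWarning, match="missing purity"):
            _, kept, _ = filter_by_purity(m, clin, allow_missing=True)
        assert [r.sample_id for r in kept] == ["S0"]


class TestBatchCorrect:
    def test_planted_offsets_removed(self, rng):
        base = rng.normal(size=(10, 40))
        vals = base.copy()
        vals[:, :20] += 5.0
        vals[:, 20:] -= 5.0
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"G{i}" for i in range(10)],
                         columns=[f"S{j}" for j in range(40)]),
            scale_tag="standardized",
        )
        cohorts = {f"S{j}": ("A" if j < 20 else "B") for j in range(40)}
        out = batch_correct(m, cohorts)
        assert np.all(np.abs(out.values.mean(axis=1)) < 1e-9)
        assert out.scale_tag == "standardized"
        # no single gene predicts the cohort after correction
        a = out.values.iloc[:, :20].to_numpy()
        b = out.values.iloc[:, 20:].to_numpy()
        t = (a.mean(1) - b.mean(1)) / np.sqrt(a.var(1, ddof=1) / 20 + b.var(1, ddof=1) / 20)
        assert np.median(np.abs(t)) < 2.0

    def test_single_cohort_is_global_zscore(self, rng):
        vals = rng.normal(size=(5, 10))
        m = ExpressionMatrix(
            pd.DataFrame(vals, index=[f"G{i}" for i in range(5)],
                         columns=[f"S{j}" for j in range(10)]),
            scale_tag="standardized",
        )
        out = batch_correct(m, {f"S{j}": "A" for j in range(10)})
        expect = (vals - vals.mean(1, keepdims=True)) / vals.std(1, ddof=1, keepdims=True)
        assert np.allclose(out.values.to_numpy(), expect)

    def test_constant_gene_zeroed_with_warning(self):
        m = ExpressionMatrix(
            pd.DataFrame([[3.0, 3.0, 3.0]], index=["G0"], columns=["S0", "S1", "S2"]),
            scale_tag="standardized",
        )
        with pytest.warns(UserWarning, match="zero variance"):
            out = batch_correct(m, {"S0": "A", "S1": "A", "S2": "A"})
        assert np.all(out.values.to_numpy() == 0.0)

    def test_tiny_cohort_rejected(self):
        m = counts_matrix(np.ones((1, 3)))
        with pytest.raises(ValueError, match="fewer than 2"):
            batch_correct(m, {"S0": "A", "S1": "B", "S2": "B"})


class TestLog2fcScreen:
    def _matrix(self, diffs_log10):
        # group a elevated by diff (log10 scale) over group b
        rows = [[d, d, 0.0, 0.0] for d in diffs_log10]
        return ExpressionMatrix(
            pd.DataFrame(rows, index=[f"G{i}" for i in range(len(rows))],
                         columns=["A1", "A2", "B1", "B2"]),
            scale_tag="log10tpm",
        )

    def test_threshold_is_inclusive(self):
        lg = np.log10(2.0)  # exactly 1.0 on the log2 scale
        m = self._matrix([lg, lg * 0.999, lg * 1.5])
        hits = log2fc_screen(m, ["A1", "A2"], ["B1", "B2"])
        assert hits == ["G0", "G2"]

    def test_identical_groups_empty(self):
        m = self._matrix([0.0, 0.0])
        assert log2fc_screen(m, ["A1", "A2"], ["B1", "B2"]) == []

    def test_zero_threshold_returns_all(self):
        m = self._matrix([0.0, 1.0])
        cfg = PreprocessConfig(log2fc_threshold=0.0)
        assert log2fc_screen(m, ["A1", "A2"], ["B1", "B2"], cfg) == ["G0", "G1"]

    def test_overlapping_groups_rejected(self):
        m = self._matrix([1.0])
        with pytest.raises(ValueError, match="disjoint"):
            log2fc_screen(m, ["A1"], ["A1", "B1"])
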