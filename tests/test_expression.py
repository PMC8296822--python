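"""Differential expression: I/O contracts, moderation, DEG thresholds."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from dcnet import (
    ExpressionMatrix,
    ModerationParams,
    call_degs,
    estimate_moderation,
    log2_fold_change,
    read_expression,
)
from dcnet.expression import ExpressionFormatError, deg_set, moderated_t

from conftest import make_matrix


def _write(tmp_path, matrix_text, cmap_text):
    m = tmp_path / "expr.tsv"
    c = tmp_path / "cond.tsv"
    m.write_text(matrix_text)
    c.write_text(cmap_text)
    return m, c


CMAP4 = "sample_id\tcondition\ns1\thealthy\ns2\thealthy\ns3\tdisease\ns4\tdisease\n"


class TestReadExpression:
    def test_well_formed_matrix(self, tmp_path):
        m, c = _write(
            tmp_path,
            "gene_id\ts1\ts2\ts3\ts4\nA\t1\t2\t3\t4\nB\t1\t1\t2\t2\nC\t5\t5\t5\t5\n",
            CMAP4,
        )
        matrix = read_expression(m, c)
        assert matrix.data.shape == (3, 4)
        assert matrix.samples("healthy") == ["s1", "s2"]

    def test_duplicate_gene_named_in_error(self, tmp_path):
        m, c = _write(
            tmp_path,
            "gene_id\ts1\ts2\ts3\ts4\nA\t1\t2\t3\t4\nA\t1\t1\t2\t2\n",
            CMAP4,
        )
        with pytest.raises(ExpressionFormatError, match="'A'"):
            read_expression(m, c)

    def test_missing_sample_named_in_error(self, tmp_path):
        m, c = _write(
            tmp_path,
            "gene_id\ts1\ts2\ts3\ts9\nA\t1\t2\t3\t4\n",
            CMAP4,
        )
        with pytest.raises(ExpressionFormatError, match="'s9'"):
            read_expression(m, c)

    def test_non_numeric_cell_rejected(self, tmp_path):
        m, c = _write(
            tmp_path,
            "gene_id\ts1\ts2\ts3\ts4\nA\t1\tx\t3\t4\n",
            CMAP4,
        )
        with pytest.raises(ExpressionFormatError, match="s2"):
            read_expression(m, c)

    def test_unknown_condition_label_rejected(self, tmp_path):
        m, c = _write(
            tmp_path,
            "gene_id\ts1\ts2\ts3\ts4\nA\t1\t2\t3\t4\n",
            CMAP4.replace("disease", "sick"),
        )
        with pytest.raises(ExpressionFormatError, match="sick"):
            read_expression(m, c)


class TestLog2FoldChange:
    def test_hand_computed_values(self):
        matrix = make_matrix(
            {"A": [1, 1, 1, 2, 2, 2], "B": [3, 3, 3, 3, 3, 3], "C": [5.0, 5.4, 4.0, 4.4, 4.0, 4.4]},
            n_healthy=3,
        )
        lfc = log2_fold_change(matrix)
        assert lfc["A"] == pytest.approx(1.0)
        assert lfc["B"] == pytest.approx(0.0)
        matrix2 = make_matrix({"C": [5.0, 5.4, 4.0, 4.4]}, n_healthy=2)
        assert log2_fold_change(matrix2)["C"] == pytest.approx(-1.0)

    def test_sign_convention_disease_minus_healthy(self):
        matrix = make_matrix({"A": [1, 1, 3, 3]}, n_healthy=2)
        assert log2_fold_change(matrix)["A"] == pytest.approx(2.0)


class TestModeration:
    def test_zero_prior_df_reduces_to_per_gene_variance(self):
        params = ModerationParams(prior_df=0.0, prior_var=1.0, residual_df=4)
        s2 = np.array([0.1, 0.5, 2.0])
        np.testing.assert_allclose(params.posterior_var(s2), s2)

    def test_infinite_prior_df_pools_completely(self):
        params = ModerationParams(prior_df=math.inf, prior_var=0.7, residual_df=4)
        np.testing.assert_allclose(
            params.posterior_var(np.array([0.1, 0.5, 2.0])), 0.7
        )

    def test_parameter_recovery_from_hierarchical_draws(self, rng):
        # true prior: scaled inverse chi-square, s0^2 = 0.25, d0 = 4; observed
        # sample variances on 4 residual df
        s0_sq, d0, df = 0.25, 4, 4
        sigma2 = s0_sq * d0 / rng.chisquare(d0, size=500)
        s2 = sigma2 * rng.chisquare(df, size=500) / df
        params = estimate_moderation(s2, df)
        assert 2 <= params.prior_df <= 8
        assert 0.15 <= params.prior_var <= 0.40

    def test_equal_variances_give_infinite_prior_df(self):
        params = estimate_moderation(np.full(10, 0.5), 4)
        assert math.isinf(params.prior_df)
        np.testing.assert_allclose(params.posterior_var(np.full(10, 0.5)), 0.5)

    def test_moderated_t_with_zero_prior_equals_pooled_t(self, rng):
        data = rng.normal(8, 1, size=(50, 12))
        samples = [f"s{i}" for i in range(12)]
        matrix = ExpressionMatrix(
            pd.DataFrame(data, index=[f"G{i}" for i in range(50)], columns=samples),
            pd.Series(["healthy"] * 6 + ["disease"] * 6, index=samples),
        )
        table = moderated_t(matrix, ModerationParams(0.0, 1.0, 10))
        t_ref, p_ref = stats.ttest_ind(data[:, 6:], data[:, :6], axis=1, equal_var=True)
        np.testing.assert_allclose(table["t"].to_numpy(), t_ref, atol=1e-10)
        np.testing.assert_allclose(table["p"].to_numpy(), p_ref, atol=1e-10)


class TestCallDegs:
    def test_strict_threshold_boundaries(self):
        # |log2fc| must strictly exceed 0.5: an exact 0.5 shift with tiny
        # within-group noise is not a DEG however small its p
        matrix = make_matrix(
            {
                # binary-exact values: condition means 1.0 and 1.5, lfc 0.5 exact
                "EXACT": [1.0, 1.25, 0.75, 1.5, 1.75, 1.25],
                "WEAK": [1.0, 1.4, 0.6, 1.8, 2.2, 1.4],
                "GOOD": [1.0, 1.01, 0.99, 2.0, 2.01, 1.99],
            },
            n_healthy=3,
        )
        table = call_degs(matrix, method="welch")
        assert table.loc["EXACT", "log2fc"] == pytest.approx(0.5)
        assert not table.loc["EXACT", "is_deg"]
        assert table.loc["WEAK", "p"] > 0.05 and not table.loc["WEAK", "is_deg"]
        assert bool(table.loc["GOOD", "is_deg"])
        assert deg_set(table) == {"GOOD"}

    def test_type_i_error_rate_on_null_genes(self, rng):
        data = rng.normal(8, 0.5, size=(1000, 12))
        samples = [f"s{i}" for i in range(12)]
        matrix = ExpressionMatrix(
            pd.DataFrame(data, index=[f"G{i}" for i in range(1000)], columns=samples),
            pd.Series(["healthy"] * 6 + ["disease"] * 6, index=samples),
        )
        table = call_degs(matrix, method="welch")
        frac = float((table["p"] < 0.05).mean())
        lo, hi = stats.binom.ppf([0.005, 0.995], 1000, 0.05) / 1000
        assert lo <= frac <= hi

    def test_label_swap_negates_lfc_and_preserves_p(self, rng):
        data = rng.normal(8, 1, size=(30, 10))
        samples = [f"s{i}" for i in range(10)]
        cond = pd.Series(["healthy"] * 5 + ["disease"] * 5, index=samples)
        swapped = cond.map({"healthy": "disease", "disease": "healthy"})
        frame = pd.DataFrame(data, index=[f"G{i}" for i in range(30)], columns=samples)
        t1 = call_degs(ExpressionMatrix(frame, cond), method="moderated")
        t2 = call_degs(ExpressionMatrix(frame, swapped), method="moderated")
        np.testing.assert_allclose(t1["log2fc"], -t2["log2fc"])
        np.testing.assert_allclose(t1["p"], t2["p"], rtol=1e-12)

    def test_within_condition_sample_permutation_is_irrelevant(self, rng):
        data = rng.normal(8, 1, size=(30, 10))
        samples = [f"s{i}" for i in range(10)]
        cond = pd.Series(["healthy"] * 5 + ["disease"] * 5, index=samples)
        frame = pd.DataFrame(data, index=[f"G{i}" for i in range(30)], columns=samples)
        shuffled = frame[["s3", "s1", "s0", "s4", "s2", "s8", "s9", "s5", "s7", "s6"]]
        t1 = call_degs(ExpressionMatrix(frame, cond), method="moderated")
        t2 = call_degs(ExpressionMatrix(shuffled, cond), method="moderated")
        np.testing.assert_allclose(t1["p"], t2["p"], rtol=1e-12)

    def test_too_few_samples_rejected(self):
        matrix = make_matrix({"A": [1.0, 2.0, 3.0]}, n_healthy=1)
        with pytest.raises(ValueError, match="two samples"):
            call_degs(matrix, method="moderated")

    def test_unknown_method_rejected(self):
        matrix = make_matrix({"A": [1.0, 2.0, 3.0, 4.0]}, n_healthy=2)
        with pytest.raises(ValueError, match="unknown method"):
            call_degs(matrix, method="limma")

    def test_fdr_column_optional(self, rng):
        data = rng.normal(8, 1, size=(20, 8))
        samples = [f"s{i}" for i in range(8)]
        matrix = ExpressionMatrix(
            pd.DataFrame(data, index=[f"G{i}" for i in range(20)], columns=samples),
            pd.Series(["healthy"] * 4 + ["disease"] * 4, index=samples),
        )
        assert "q" not in call_degs(matrix).columns
        table = call_degs(matrix, fdr=True)
        assert (table["q"] >= table["p"] - 1e-15).all()
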