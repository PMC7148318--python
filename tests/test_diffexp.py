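import math
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from egfr_impact import (
    ExpressionMatrix,
    ModerationParameters,
    exclude_kras_mutants,
    filter_degs,
    moderated_t_test,
)
from egfr_impact.diffexp import estimate_moderation


def _oracle_moderated_t(mut: np.ndarray, wt: np.ndarray, d0: float, s0_sq: float):
    """Direct single-gene evaluation of the moderated-t formulas."""
    n1, n2 = mut.size, wt.size
    dg = n1 + n2 - 2
    diff = mut.mean() - wt.mean()
    s2 = ((n1 - 1) * mut.var(ddof=1) + (n2 - 1) * wt.var(ddof=1)) / dg
    if math.isinf(d0):
        s2_post = s0_sq
    else:
        s2_post = (d0 * s0_sq + dg * s2) / (d0 + dg)
    t = diff / math.sqrt(s2_post * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(abs(t), df=d0 + dg)
    return t, p


class TestExcludeKras:
    def _cohort(self, kras):
        n = len(kras)
        samples = [f"s{i}" for i in range(n)]
        df = pd.DataFrame(
            np.arange(2 * n, dtype=float).reshape(2, n),
            index=["gA", "gB"],
            columns=samples,
        )
        annot = pd.DataFrame({"kras_status": kras}, index=samples)
        return ExpressionMatrix(df), annot

    def test_mutants_dropped_order_preserved(self):
        m, a = self._cohort(["wild_type"] * 4 + ["mutant"] * 3 + ["wild_type"] * 3)
        out, annot = exclude_kras_mutants(m, a)
        assert out.n_samples == 7
        assert out.sample_ids == [f"s{i}" for i in [0, 1, 2, 3, 7, 8, 9]]
        assert (annot["kras_status"] != "mutant").all()

    def test_no_mutants_is_identity(self):
        m, a = self._cohort(["wild_type"] * 5)
        out, _ = exclude_kras_mutants(m, a)
        pd.testing.assert_frame_equal(out.data, m.data)

    def test_all_mutants_errors(self):
        m, a = self._cohort(["mutant"] * 4)
        with pytest.raises(ValueError, match="no samples remain"):
            exclude_kras_mutants(m, a)

    def test_missing_annotation_names_sample(self):
        m, a = self._cohort(["wild_type"] * 4)
        with pytest.raises(KeyError, match="s3"):
            exclude_kras_mutants(m, a.drop(index="s3"))


class TestModeratedT:
    def test_identical_groups_give_t0_p1(self, two_group_matrix):
        matrix, labels = two_group_matrix
        df = matrix.data.copy()
        df.iloc[0] = np.tile(df.iloc[0, :10].to_numpy(), 2)  # mutant == wt values
        df.iloc[0, 10:] = df.iloc[0, :10].to_numpy()
        res = moderated_t_test(ExpressionMatrix(df), labels)
        assert res.loc[0, "t_stat"] == 0.0
        assert res.loc[0, "p_value"] == 1.0

    def test_matches_single_gene_oracle(self, two_group_matrix):
        matrix, labels = two_group_matrix
        res = moderated_t_test(matrix, labels)
        mod = res.attrs["moderation"]
        for i, gene in enumerate(matrix.gene_ids):
            mut = matrix.data.loc[gene, labels].to_numpy()
            wt = matrix.data.loc[gene, ~labels].to_numpy()
            t, p = _oracle_moderated_t(mut, wt, mod.d0, mod.s0_sq)
            assert res.loc[i, "t_stat"] == pytest.approx(t, abs=1e-10)
            assert res.loc[i, "p_value"] == pytest.approx(p, abs=1e-10)

    def test_d0_infinity_limit_is_zlike(self, two_group_matrix):
        matrix, labels = two_group_matrix
        prior = ModerationParameters(d0=math.inf, s0_sq=0.64, per_gene_df=18)
        res = moderated_t_test(matrix, labels, prior=prior)
        diff = matrix.data.loc[:, labels.to_numpy()].mean(axis=1) - matrix.data.loc[
            :, (~labels).to_numpy()
        ].mean(axis=1)
        expected = diff.to_numpy() / np.sqrt(0.64 * (1 / 10 + 1 / 10))
        np.testing.assert_allclose(res["t_stat"].to_numpy(), expected, atol=1e-12)

    def test_no_moderation_equals_student_t(self, two_group_matrix):
        matrix, labels = two_group_matrix
        res = moderated_t_test(matrix, labels, moderation=False)
        ref = stats.ttest_ind(
            matrix.data.loc[:, labels.to_numpy()],
            matrix.data.loc[:, (~labels).to_numpy()],
            axis=1,
            equal_var=True,
        )
        np.testing.assert_allclose(res["t_stat"].to_numpy(), ref.statistic, atol=1e-10)
        np.testing.assert_allclose(res["p_value"].to_numpy(), ref.pvalue, atol=1e-10)

    def test_label_swap_negates_logfc_and_t(self, two_group_matrix):
        matrix, labels = two_group_matrix
        a = moderated_t_test(matrix, labels)
        b = moderated_t_test(matrix, ~labels)
        np.testing.assert_allclose(a["log_fc"], -b["log_fc"], atol=1e-12)
        np.testing.assert_allclose(a["t_stat"], -b["t_stat"], atol=1e-12)
        np.testing.assert_allclose(a["p_value"], b["p_value"], atol=1e-12)

    def test_row_shift_invariance(self, two_group_matrix):
        matrix, labels = two_group_matrix
        shifted = matrix.data.copy()
        shifted.iloc[5] += 100.0
        a = moderated_t_test(matrix, labels)
        b = moderated_t_test(ExpressionMatrix(shifted), labels)
        assert a.loc[5, "t_stat"] == pytest.approx(b.loc[5, "t_stat"], abs=1e-9)
        assert a.loc[5, "p_value"] == pytest.approx(b.loc[5, "p_value"], abs=1e-9)

    def test_small_group_rejected(self, two_group_matrix):
        matrix, _ = two_group_matrix
        labels = pd.Series([True] + [False] * 19, index=matrix.sample_ids)
        with pytest.raises(ValueError, match=">=2 samples"):
            moderated_t_test(matrix, labels)

    def test_fold_change_consistent_with_logfc(self, two_group_matrix):
        matrix, labels = two_group_matrix
        res = moderated_t_test(matrix, labels)
        np.testing.assert_allclose(res["fold_change"], 2 ** res["log_fc"], rtol=1e-12)
        assert ((res["direction"] == "up") == (res["log_fc"] > 0)).all()


def test_moderated_t_matches_limma(tmp_path, two_group_matrix):
    """Cross-check against the Bioconductor reference on a small fixture."""
    matrix, labels = two_group_matrix
    expr = tmp_path / "expr.tsv"
    matrix.data.to_csv(expr, sep="\t")
    out = tmp_path / "limma.tsv"
    script = textwrap.dedent(
        f"""
        suppressMessages(library(limma))
        x <- as.matrix(read.delim("{expr}", row.names = 1, check.names = FALSE))
        group <- factor(c(rep("mut", 10), rep("wt", 10)), levels = c("wt", "mut"))
        fit <- eBayes(lmFit(x, model.matrix(~group)))
        write.table(data.frame(t = fit$t[, 2], p = fit$p.value[, 2]),
                    "{out}", sep = "\t", quote = FALSE)
        """
    )
    r = subprocess.run(
        ["Rscript", "-e", script], capture_output=True, text=True, timeout=300
    )
    assert r.returncode == 0, r.stderr
    ref = pd.read_csv(out, sep="\t", index_col=0)
    res = moderated_t_test(matrix, labels).set_index("gene_id")
    np.testing.assert_allclose(res["t_stat"], ref["t"], rtol=1e-4)
    np.testing.assert_allclose(res["p_value"], ref["p"], rtol=1e-4)


class TestEstimateModeration:
    def test_recovers_prior_from_large_sample(self):
        rng = np.random.default_rng(5)
        d0, s0_sq, dg = 8.0, 0.25, 10
        true_var = s0_sq * d0 / rng.chisquare(d0, size=20000)
        s2 = true_var * rng.chisquare(dg, size=20000) / dg
        fit = estimate_moderation(s2, dg)
        assert fit.d0 == pytest.approx(d0, rel=0.1)
        assert fit.s0_sq == pytest.approx(s0_sq, rel=0.05)

    def test_homogeneous_variances_give_infinite_d0(self):
        rng = np.random.default_rng(6)
        s2 = 0.5 * rng.chisquare(18, size=5000) / 18
        fit = estimate_moderation(s2, 18)
        assert math.isinf(fit.d0)
        assert fit.s0_sq == pytest.approx(0.5, rel=0.05)


class TestFilterDegs:
    @pytest.mark.parametrize(
        "p,fc,kept",
        [
            (0.005, 1.5, True),
            (0.005, 1.2, False),  # fold change exactly at bound: strict >
            (0.01, 2.0, False),  # p exactly at bound: strict <
            (0.005, 1 / 1.3, True),
            (0.005, 1 / 1.2, False),
        ],
    )
    def test_strict_boundaries(self, p, fc, kept):
        rec = pd.DataFrame(
            {"gene_id": ["g"], "p_value": [p], "fold_change": [fc]}
        )
        assert (len(filter_degs(rec)) == 1) is kept

    @pytest.mark.parametrize("kwargs", [{"p_max": 0.0}, {"p_max": 1.5}, {"fc_min": 1.0}])
    def test_parameter_validation(self, kwargs):
        rec = pd.DataFrame({"gene_id": ["g"], "p_value": [0.5], "fold_change": [1.0]})
        with pytest.raises(ValueError):
            filter_degs(rec, **kwargs)
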