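import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from conftest import small_matrix
from oracles import step_up_bh
from hubnet.diffexpr import (
    DifferentialExpression,
    RVMFitError,
    RVMModel,
    bh_fdr,
    fit_rvm,
    fold_change,
    geometric_mean,
    ordinary_t_test,
    rvm_t_test,
    select_differential,
    volcano_coordinates,
    _rvm_negloglik,
)


class TestGeometricMean:
    @pytest.mark.parametrize(
        "values, expected",
        [((4, 4, 4), 4.0), ((2, 8), 4.0), ((56.08,), 56.08)],
    )
    def test_closed_forms(self, values, expected):
        assert geometric_mean(values) == pytest.approx(expected)

    @pytest.mark.parametrize("bad", [(), (1.0, 0.0), (-2.0,)])
    def test_domain_errors(self, bad):
        with pytest.raises(ValueError):
            geometric_mean(bad)


class TestFoldChange:
    @pytest.mark.parametrize(
        "gm_exp, gm_ctrl, rounded, trend",
        [(2650.31, 56.08, 47.26, "up"), (341.48, 785.22, 0.43, "down")],
    )
    def test_report_rows(self, gm_exp, gm_ctrl, rounded, trend):
        ratio, t = fold_change(gm_exp, gm_ctrl)
        assert round(ratio, 2) == rounded
        assert t == trend

    def test_tie_is_flat(self):
        assert fold_change(10.0, 10.0) == (1.0, "flat")

    def test_domain_error(self):
        with pytest.raises(ValueError):
            fold_change(0.0, 1.0)


class TestFitRVM:
    def test_parameter_recovery(self):
        # variances drawn from the model itself at a=2, b=1, df=4
        rng = np.random.default_rng(5)
        precision = rng.gamma(2.0, 1.0, size=5000)
        s2 = (1.0 / precision) * rng.chisquare(4, size=5000) / 4.0
        model = fit_rvm(s2, df=4)
        assert 1.6 <= model.a <= 2.4

    def test_constant_variances_rejected(self):
        with pytest.raises(RVMFitError):
            fit_rvm(np.full(100, 0.5), df=4)

    def test_too_few_genes_rejected(self):
        with pytest.raises(RVMFitError):
            fit_rvm(np.linspace(0.1, 1, 20), df=4)

    def test_fit_is_local_optimum(self, rng):
        precision = rng.gamma(3.0, 0.5, size=2000)
        s2 = (1.0 / precision) * rng.chisquare(4, size=2000) / 4.0
        model = fit_rvm(s2, df=4)
        best = _rvm_negloglik(np.log([model.a, model.b]), s2, 4)
        for _ in range(20):
            jitter = rng.normal(0, 0.3, size=2)
            perturbed = _rvm_negloglik(np.log([model.a, model.b]) + jitter, s2, 4)
            assert best <= perturbed + 1e-9


class TestRVMTTest:
    def test_zero_variance_equal_means_gives_p_one(self):
        matrix = small_matrix({"g1": [5, 5, 5, 5, 5, 5]})
        model = RVMModel(a=2.0, b=1.0, df_residual=4)
        out = rvm_t_test(matrix, model)
        assert out.loc["g1", "statistic"] == 0.0
        assert out.loc["g1", "p_value"] == 1.0

    def test_flat_prior_limit_matches_pooled_t(self, rng):
        # a -> 0 with 1/b -> 0: moderation vanishes and df -> residual df
        genes = {f"g{i}": 2.0 ** rng.normal(8, 1, size=6) for i in range(500)}
        matrix = small_matrix(genes)
        flat = RVMModel(a=1e-9, b=1e12, df_residual=4)
        moderated = rvm_t_test(matrix, flat)
        log2 = matrix.log2()
        ref = stats.ttest_ind(
            log2[matrix.samples_of("experimental")],
            log2[matrix.samples_of("control")],
            axis=1,
            equal_var=True,
        )
        assert np.max(np.abs(moderated["p_value"].to_numpy() - ref.pvalue)) < 1e-3

    def test_group_with_one_sample_rejected(self):
        import pandas as pd

        from hubnet.diffexpr import CONTROL, EXPERIMENTAL, ExpressionMatrix

        data = pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"], columns=["a", "b", "c"])
        groups = pd.Series(
            [CONTROL, CONTROL, EXPERIMENTAL], index=["a", "b", "c"]
        )
        with pytest.raises(ValueError):
            ordinary_t_test(ExpressionMatrix(data, groups))


class TestBHFDR:
    def test_hand_example(self):
        out = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate(self):
        assert bh_fdr([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)

    def test_nan_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.1, float("nan")])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    def test_matches_step_up_oracle(self, p):
        assert np.allclose(bh_fdr(p), step_up_bh(p), atol=1e-12)


class TestSelection:
    def _records(self, rows):
        return pd.DataFrame(
            rows,
            columns=["gene", "p_value", "fdr", "geom_mean_exp", "geom_mean_ctrl", "fold_change", "trend"],
        )

    def test_boundary_is_strict(self):
        rec = self._records([("g1", 0.05, 0.01, 2, 1, 2.0, "up")])
        assert select_differential(rec).empty

    def test_empty_input(self):
        assert select_differential(self._records([])).empty

    def test_sorted_by_p_then_effect(self):
        rec = self._records(
            [
                ("a", 0.01, 0.01, 2, 1, 2.0, "up"),
                ("b", 0.001, 0.001, 8, 1, 8.0, "up"),
                ("c", 0.01, 0.01, 1, 4, 0.25, "down"),
            ]
        )
        out = select_differential(rec)
        assert list(out["gene"]) == ["b", "c", "a"]


class TestVolcano:
    def test_closed_forms(self):
        rec = pd.DataFrame(
            {
                "gene": ["a", "b", "c"],
                "p_value": [0.5, 1e-8, 1.0],
                "fold_change": [1.0, 47.26, 4.0],
            }
        )
        out = volcano_coordinates(rec)
        assert out.loc[0, "log2_fold_change"] == 0.0
        assert out.loc[1, "log2_fold_change"] == pytest.approx(5.563, abs=1e-3)
        assert out.loc[2, "neg_log10_p"] == 0.0

    def test_p_floor_keeps_coordinates_finite(self):
        rec = pd.DataFrame({"gene": ["a"], "p_value": [0.0], "fold_change": [2.0]})
        assert np.isfinite(volcano_coordinates(rec)["neg_log10_p"]).all()


class TestInvariances:
    def test_sample_permutation_leaves_statistics_unchanged(self, rng):
        genes = {f"g{i}": 2.0 ** rng.normal(8, 1, size=6) for i in range(60)}
        matrix = small_matrix(genes)
        res = DifferentialExpression(matrix).fit(method="t")
        # reorder the columns of the same frame; the labels travel along
        perm = ["c2", "c0", "c1", "e1", "e2", "e0"]
        data = matrix.data[perm]
        from hubnet.diffexpr import ExpressionMatrix

        res2 = DifferentialExpression(ExpressionMatrix(data, matrix.groups[perm])).fit(method="t")
        assert np.allclose(res.records["p_value"], res2.records["p_value"])
        assert np.allclose(res.records["fold_change"], res2.records["fold_change"])

    def test_label_swap_inverts_folds_and_preserves_p(self, rng):
        genes = {f"g{i}": 2.0 ** rng.normal(8, 1, size=6) for i in range(60)}
        matrix = small_matrix(genes)
        res = DifferentialExpression(matrix).fit(method="t")
        swapped = DifferentialExpression(matrix.swap_groups()).fit(method="t")
        assert np.allclose(
            res.records["fold_change"] * swapped.records["fold_change"], 1.0
        )
        assert np.allclose(res.records["p_value"], swapped.records["p_value"])
        flips = {"up": "down", "down": "up", "flat": "flat"}
        assert all(
            flips[a] == b
            for a, b in zip(res.records["trend"], swapped.records["trend"])
        )


def test_summary_reports_counts(default_sim):
    _, matrix, truth = default_sim
    res = DifferentialExpression(matrix).fit()
    text = res.summary()
    assert "RVM moderated" in text
    assert f"genes tested:            {len(matrix.gene_ids)}" in text
    assert res.rvm is not None and res.rvm.a > 0
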