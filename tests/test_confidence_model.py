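import numpy as np
import pandas as pd
import pytest

from ddikit.confidence_model import (
    LogisticApprovalModel,
    bootstrap_auc_compare,
    compare_nested,
    complete_rows,
    decile_calibration,
    fit_logistic,
    hosmer_lemeshow,
    loocv_roc,
    loocv_scores,
    odds_ratios,
    stepwise_reduce,
    zscore_probability_map,
)
from ddikit.errors import CollinearityError, DegenerateDataError, StateError
from ddikit.synthetic_data import BenchmarkConfig, gen_benchmark_table

FULL_VARS = ["zscore_3did", "af_dockq", "iupred_interface"]


def table_from(x, y, name="x"):
    return pd.DataFrame(
        {name: x, "label": np.where(y, "approved", "nonapproved")}
    )


class TestFitting:
    def test_intercept_only_balanced_labels(self):
        tab = table_from(np.zeros(20), np.repeat([0, 1], 10))
        fit = fit_logistic(tab, [])
        assert fit.params[0] == pytest.approx(0.0, abs=1e-8)

    def test_planted_coefficients_inside_wald_ci(self):
        tab, _ = gen_benchmark_table(
            BenchmarkConfig(seed=12, n_rows=500, intercept=-3.0,
                            coefficients=(("zscore_3did", 0.7),),
                            n_engineered=0)
        )
        fit = fit_logistic(tab, ["zscore_3did"])
        # single replicate: allow 3 SE so only a broken estimator trips this;
        # nominal 95% CI coverage is checked over replicates elsewhere
        for truth, est, se in zip([-3.0, 0.7], fit.params, fit.bse):
            assert abs(est - truth) <= 3 * se
        assert fit.converged and not fit.separation_warning

    def test_perfect_separation_flagged(self):
        tab = table_from([0.0, 1, 2, 10, 11, 12], [0, 0, 0, 1, 1, 1])
        fit = fit_logistic(tab, ["x"])
        assert fit.separation_warning

    def test_single_class_rejected(self):
        tab = table_from(np.arange(6.0), np.ones(6))
        with pytest.raises(DegenerateDataError):
            fit_logistic(tab, ["x"])

    def test_collinear_design_names_columns(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=40)
        tab = table_from(x, rng.random(40) < 0.5)
        tab["x2"] = 2 * tab["x"]  # exact linear duplicate
        with pytest.raises(CollinearityError) as err:
            fit_logistic(tab, ["x", "x2"])
        assert set(err.value.offending_columns) & {"x", "x2"}

    def test_sklearn_interface(self):
        tab, _ = gen_benchmark_table(BenchmarkConfig(seed=4, n_rows=100))
        est = LogisticApprovalModel(variables=["zscore_3did"])
        est.fit(tab, tab["label"].to_numpy())
        proba = est.predict_proba(tab)
        assert proba.shape == (100, 2)
        assert np.allclose(proba.sum(axis=1), 1.0)
        assert est.get_params() == {"variables": ["zscore_3did"]}
        preds = est.predict(tab)
        assert set(preds) <= {0, 1}


class TestOddsRatios:
    def test_closed_forms(self):
        tab = table_from(np.r_[np.zeros(20), np.ones(20)],
                         np.r_[np.repeat([0, 1], 10), np.repeat([0, 1], [5, 15])])
        fit = fit_logistic(tab, ["x"])
        # group odds 1:1 vs 3:1 -> OR = 3 by the 2x2 closed form
        assert odds_ratios(fit)["x"] == pytest.approx(3.0, rel=1e-6)
        assert "intercept" not in odds_ratios(fit)

    def test_balanced_groups_give_unit_odds_ratio(self):
        # identical outcome odds in both covariate groups -> coefficient 0
        tab = table_from(np.repeat([0.0, 1.0], 20), np.tile([0, 1], 20))
        fit = fit_logistic(tab, ["x"])
        assert odds_ratios(fit)["x"] == pytest.approx(1.0, abs=1e-6)


class TestStepwise:
    def test_single_variable_returned_unchanged(self, benchmark_table):
        table, _ = benchmark_table
        variables, fit = stepwise_reduce(table, ["zscore_3did"])
        assert variables == ["zscore_3did"]
        assert fit.variables == ("intercept", "zscore_3did")

    def test_pure_noise_covariate_removed_at_theoretical_rate(self):
        # AIC drops a chi2(1) noise term unless its LR stat exceeds 2;
        # closed form keeps it with prob P(chi2_1 > 2) ~= 0.157, so over
        # 100 replicates the removal count should sit near 84 (+/- 4 sd)
        removed = 0
        for rep in range(100):
            tab, _ = gen_benchmark_table(
                BenchmarkConfig(seed=30_000 + rep, n_rows=200,
                                noise_columns=("noise",))
            )
            variables, _ = stepwise_reduce(tab, FULL_VARS + ["noise"])
            removed += "noise" not in variables
        assert 70 <= removed <= 98

    def test_deterministic(self, benchmark_table):
        table, _ = benchmark_table
        runs = [stepwise_reduce(table, FULL_VARS)[0] for _ in range(2)]
        assert runs[0] == runs[1]


class TestLOOCV:
    def test_deterministic_out_of_fold_probabilities(self, benchmark_table):
        table, _ = benchmark_table
        p1, y1, ids1 = loocv_scores(table, ["zscore_3did"])
        p2, y2, ids2 = loocv_scores(table, ["zscore_3did"])
        assert np.array_equal(p1, p2) and ids1 == ids2

    def test_separable_covariate_gives_auc_one(self):
        tab = table_from(np.r_[np.arange(10.0), np.arange(100.0, 110)],
                         np.repeat([0, 1], 10))
        roc = loocv_roc(tab, ["x"])
        assert roc.auc == 1.0

    def test_auc_invariant_under_monotone_transform(self, benchmark_table):
        from sklearn.metrics import roc_auc_score

        table, _ = benchmark_table
        probs, y, _ = loocv_scores(table, ["zscore_3did"])
        assert roc_auc_score(y, probs) == pytest.approx(
            roc_auc_score(y, np.log(probs / (1 - probs))), abs=1e-12
        )

    def test_youden_threshold_maximizes_j(self, benchmark_table):
        table, _ = benchmark_table
        roc = loocv_roc(table, FULL_VARS)
        j = roc.sensitivity + roc.specificity - 1
        best = roc.youden_sensitivity + roc.youden_specificity - 1
        assert best == pytest.approx(j.max())


class TestNestedComparison:
    def test_model_compared_with_itself(self, benchmark_table):
        table, _ = benchmark_table
        fit = fit_logistic(table, ["zscore_3did"])
        cmp = compare_nested(fit, fit)
        assert cmp.statistic == 0.0 and cmp.p_value == 1.0

    def test_statistic_nonnegative_and_df_is_parameter_difference(
        self, benchmark_table
    ):
        table, _ = benchmark_table
        rows = complete_rows(table, FULL_VARS)
        small = fit_logistic(rows, ["zscore_3did"])
        big = fit_logistic(rows, FULL_VARS)
        cmp = compare_nested(small, big)
        assert cmp.statistic >= 0 and cmp.df == 2

    def test_non_nested_rejected(self, benchmark_table):
        table, _ = benchmark_table
        a = fit_logistic(table, ["af_dockq"])
        b = fit_logistic(table, ["zscore_3did", "iupred_interface"])
        with pytest.raises(StateError):
            compare_nested(a, b)

    def test_different_row_sets_rejected(self, benchmark_table):
        table, _ = benchmark_table
        small = fit_logistic(table.iloc[:70], ["zscore_3did"])
        big = fit_logistic(table, FULL_VARS)
        with pytest.raises(StateError):
            compare_nested(small, big)


class TestCalibration:
    def test_saturated_fit_gives_zero_statistic(self):
        # binary covariate + exact group frequencies: fitted probabilities
        # equal observed proportions, so every bin contributes zero
        x = np.repeat([0.0, 1.0], 20)
        y = np.r_[np.repeat([0, 1], [15, 5]), np.repeat([0, 1], [5, 15])]
        tab = table_from(x, y)
        fit = fit_logistic(tab, ["x"])
        hl = hosmer_lemeshow(fit, tab, groups=2)
        assert hl.statistic == pytest.approx(0.0, abs=1e-12)

    def test_well_specified_model_rarely_rejected(self):
        rejections = 0
        n_reps = 100
        for rep in range(n_reps):
            tab, _ = gen_benchmark_table(
                BenchmarkConfig(seed=40_000 + rep, n_rows=200,
                                coefficients=(("zscore_3did", 0.7),),
                                n_engineered=0)
            )
            fit = fit_logistic(tab, ["zscore_3did"])
            rejections += hosmer_lemeshow(fit, tab).p_value < 0.05
        assert rejections / n_reps <= 0.07

    def test_misspecified_model_detected(self):
        rejections = 0
        for rep in range(20):
            rng = np.random.default_rng(rep)
            x = rng.normal(0, 1.5, 500)
            eta = -1.0 + 1.2 * x**2
            y = rng.random(500) < 1 / (1 + np.exp(-eta))
            tab = table_from(x, y)
            fit = fit_logistic(tab, ["x"])
            rejections += hosmer_lemeshow(fit, tab).p_value < 0.05
        assert rejections / 20 > 0.5

    def test_decile_calibration_all_approved_table(self, benchmark_table):
        table, _ = benchmark_table
        fit = fit_logistic(table, ["zscore_3did"])
        forced = table.copy()
        forced["label"] = "approved"
        cal = decile_calibration(fit, forced)
        occupied = cal[cal["n"] > 0]
        assert (occupied["observed_fraction"] == 1.0).all()

    def test_decile_binning_matches_quantile_oracle(self, benchmark_table):
        table, _ = benchmark_table
        fit = fit_logistic(table, ["zscore_3did"])
        cal = decile_calibration(fit, table)
        rows = complete_rows(table, ["zscore_3did"])
        p = fit.predict_proba(rows)
        oracle = pd.qcut(p, 10, duplicates="drop")
        assert cal[cal["n"] > 0]["n"].sum() == len(p)
        assert len(cal[cal["n"] > 0]) == len(oracle.categories)

    def test_constant_predictions_collapse_to_single_bin(self):
        tab = table_from(np.zeros(40), np.tile([0, 1], 20))
        fit = fit_logistic(tab, [])
        cal = decile_calibration(fit, tab)
        assert (cal["n"] > 0).sum() == 1
        assert cal.loc[cal["n"] > 0, "n"].iloc[0] == 40


class TestZScoreProbabilityMap:
    def test_forward_inverse_identity(self, benchmark_table):
        table, _ = benchmark_table
        fit = fit_logistic(table, ["zscore_3did"])
        for z in (-5.0, 0.0, 5.0):
            p = zscore_probability_map(fit, "forward", z)
            assert zscore_probability_map(fit, "inverse", p) == pytest.approx(
                z, abs=1e-9
            )

    def test_probability_domain_enforced(self, benchmark_table):
        table, _ = benchmark_table
        fit = fit_logistic(table, ["zscore_3did"])
        for bad in (0.0, 1.0, -0.2, 1.3):
            with pytest.raises(ValueError):
                zscore_probability_map(fit, "inverse", bad)

    def test_requires_minimal_model(self, benchmark_table):
        table, _ = benchmark_table
        fit = fit_logistic(table, FULL_VARS)
        with pytest.raises(StateError):
            zscore_probability_map(fit, "forward", 2.3)


class TestBootstrapAUC:
    def test_model_against_itself_is_not_significant(self, benchmark_table):
        table, _ = benchmark_table
        p = bootstrap_auc_compare(
            table, ["zscore_3did"], ["zscore_3did"], n_boot=100, seed=0
        )
        assert p == 1.0

    def test_reproducible_under_seed(self, benchmark_table):
        table, _ = benchmark_table
        args = (table, ["zscore_3did"], FULL_VARS)
        assert bootstrap_auc_compare(*args, n_boot=200, seed=5) == \
            bootstrap_auc_compare(*args, n_boot=200, seed=5)
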