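"""IRLS logistic regression and the collinearity-exclusion rule."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm

from facit_mcid.logistic_model import (
    change_columns,
    drop_collinear,
    fit_logistic,
    run_predictor_analyses,
    to_table_frame,
)
from facit_mcid.mcid_estimation import estimate_mcid


def _two_by_two(n11, n10, n01, n00):
    x = np.array([1.0] * (n11 + n10) + [0.0] * (n01 + n00))
    y = np.array([1.0] * n11 + [0.0] * n10 + [1.0] * n01 + [0.0] * n00)
    return pd.DataFrame({"x": x}), y


class TestFitLogistic:
    @pytest.mark.parametrize("counts", [
        (10, 10, 5, 15),
        (20, 5, 8, 30),
        (3, 9, 7, 2),
    ])
    def test_two_by_two_or_equals_cross_product_ratio(self, counts):
        n11, n10, n01, n00 = counts
        design, y = _two_by_two(*counts)
        fit = fit_logistic(design, y)
        assert fit.table.loc["x", "odds_ratio"] == pytest.approx(
            (n11 * n00) / (n10 * n01), abs=1e-6)

    def test_null_predictor_ci_covers_one(self, rng):
        x = rng.normal(size=4000)
        y = (rng.random(4000) < 0.4).astype(float)
        fit = fit_logistic(pd.DataFrame({"x": x}), y)
        assert fit.table.loc["x", "ci_low"] < 1.0 < fit.table.loc["x", "ci_high"]
        assert fit.table.loc["x", "odds_ratio"] == pytest.approx(1.0, abs=0.1)

    def test_matches_statsmodels_to_high_precision(self, rng):
        X = rng.normal(size=(400, 3))
        eta = 0.8 * X[:, 0] - 0.5 * X[:, 2]
        y = (rng.random(400) < 1 / (1 + np.exp(-eta))).astype(float)
        fit = fit_logistic(pd.DataFrame(X, columns=list("abc")), y)
        ref = sm.Logit(y, sm.add_constant(X)).fit(disp=0)
        assert np.allclose(fit.table["coef"], ref.params, atol=1e-7)
        assert np.allclose(fit.table["se"], ref.bse, atol=1e-7)

    def test_loglik_never_decreases_along_irls_path(self, rng):
        for _ in range(5):
            X = rng.normal(size=(120, 4))
            y = (rng.random(120) < 0.5).astype(float)
            fit = fit_logistic(pd.DataFrame(X), y)
            path = np.array(fit.loglik_path)
            assert np.all(np.diff(path) >= -1e-9)

    def test_coefficients_rescale_with_predictor_units(self, rng):
        x = rng.normal(size=300)
        y = (rng.random(300) < 1 / (1 + np.exp(-x))).astype(float)
        a = fit_logistic(pd.DataFrame({"x": x}), y)
        b = fit_logistic(pd.DataFrame({"x": 10.0 * x}), y)
        assert b.table.loc["x", "coef"] == pytest.approx(
            a.table.loc["x", "coef"] / 10.0, rel=1e-6)

    def test_single_class_outcome_raises(self):
        with pytest.raises(ValueError, match="single class"):
            fit_logistic(pd.DataFrame({"x": [1.0, 2.0]}), [1.0, 1.0])

    def test_complete_separation_is_flagged_not_silent(self):
        x = np.array([0.0] * 15 + [1.0] * 15)
        fit = fit_logistic(pd.DataFrame({"x": x}), x.copy())
        assert fit.separation

    def test_missing_rows_dropped_and_counted(self):
        design = pd.DataFrame({"x": [1.0, np.nan, 0.0, 1.0] * 10})
        y = np.tile([1.0, 0.0, 0.0, 1.0], 10)
        fit = fit_logistic(design, y)
        assert fit.n_dropped_missing == 10
        assert fit.n == 30


class TestDropCollinear:
    def test_haq_dropped_in_favour_of_chfs(self, rng):
        chfs = rng.gamma(2, 5, 300)
        frame = pd.DataFrame({
            "chfs": chfs,
            "haq_di": np.sqrt(chfs) + 0.05 * rng.normal(size=300),
            "age": rng.normal(55, 12, 300),
        })
        kept, report = drop_collinear(frame)
        assert kept == ["chfs", "age"]
        assert report[0]["dropped"] == "haq_di"
        assert abs(report[0]["rho"]) >= 0.7

    def test_uncorrelated_set_unchanged(self, rng):
        frame = pd.DataFrame(rng.normal(size=(200, 4)), columns=list("abcd"))
        kept, report = drop_collinear(frame)
        assert kept == list("abcd") and report == []

    def test_three_mutually_collinear_leave_one_survivor(self, rng):
        base = rng.normal(size=250)
        frame = pd.DataFrame({
            "c": base + 0.01 * rng.normal(size=250),
            "a": base,
            "b": base + 0.01 * rng.normal(size=250),
        })
        kept, report = drop_collinear(frame, priority=("a", "b", "c"))
        assert kept == ["a"]
        assert len(report) == 2


class TestPredictorAnalyses:
    def test_four_models_produced_on_a_cohort(self, default_cohort):
        analysis = estimate_mcid(default_cohort)
        results = run_predictor_analyses(default_cohort, analysis.labels)
        assert set(results) == {(d, s) for d in ("worsened", "improved")
                                for s in ("baseline", "change")}
        for fit in results.values():
            assert not isinstance(fit, Exception)
        table = to_table_frame(results)
        assert table["predictor"].notna().all()
        # HAQ-DI never survives next to CHFS in these cohorts
        assert "haq_di" not in set(table["predictor"])
        assert not table["predictor"].str.contains("d_haq").any()

    def test_empty_direction_errors_are_isolated(self, default_cohort):
        analysis = estimate_mcid(default_cohort)
        labels = analysis.labels.copy()
        labels.loc[labels["label"] == "improved", "label"] = "unchanged"
        results = run_predictor_analyses(default_cohort, labels)
        assert isinstance(results[("improved", "baseline")], ValueError)
        assert not isinstance(results[("worsened", "baseline")], Exception)
        table = to_table_frame(results)
        assert table["error"].notna().any()

    def test_change_columns_are_followup_minus_baseline(self, default_cohort):
        deltas = change_columns(default_cohort, ["chfs", "hgb"])
        manual = default_cohort["chfs_fu"] - default_cohort["chfs_base"]
        assert np.allclose(deltas["d_chfs"], manual)
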