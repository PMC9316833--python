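"""OLS fitting, cross-validation, external metrics, AD and criteria."""

import numpy as np
import pandas as pd
import pytest

from _oracles import loo_q2_bruteforce
from ht6qsar import validation
from ht6qsar.validation import (ADReport, IncompleteReportError, MLRModel,
                                SingularityError, ValidationReport,
                                applicability_domain, ccc, criteria_check,
                                external_metrics, fit_mlr, internal_metrics,
                                leverage_cutoff, loo_predictions, q2_lmo,
                                q2_loo, random_split, validate_model,
                                y_scrambling)

# printed validation battery of the published six-descriptor model
TABLE2 = {
    "r2_tr": 0.783, "r2_adj": 0.781, "rmse_tr": 0.419, "mae_tr": 0.350,
    "ccc_tr": 0.878, "q2_loo": 0.780, "rmse_cv": 0.422, "mae_cv": 0.352,
    "ccc_cv": 0.876, "q2_lmo": 0.779, "r2_yscr": 0.006, "rmse_ex": 0.425,
    "mae_ex": 0.357, "r2_ex": 0.772, "q2_f1": 0.768, "q2_f2": 0.768,
    "q2_f3": 0.777, "ccc_ex": 0.871,
}


def _noisy(n=60, p=3, sd=0.3, seed=0):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(rng.normal(size=(n, p)), columns=[f"x{i}" for i in range(p)])
    beta = np.arange(1, p + 1, dtype=float)
    y = 2.0 + X.to_numpy() @ beta + rng.normal(scale=sd, size=n)
    return X, y, beta


class TestFitMLR:
    def test_exact_linear_data_fits_perfectly(self):
        X, y, _ = _noisy(sd=0.0)
        model = fit_mlr(X, y)
        assert internal_metrics(model, X, y)["r2_tr"] == pytest.approx(1.0)

    def test_single_column_slope_and_intercept(self):
        x = np.arange(1.0, 9.0)
        model = fit_mlr(x[:, None], 2 * x)
        assert model.coefficients["x0"] == pytest.approx(2.0)
        assert model.intercept == pytest.approx(0.0, abs=1e-10)

    def test_coefficients_within_three_std_errors(self):
        X, y, beta = _noisy(n=200, sd=0.1, seed=1)
        model = fit_mlr(X, y)
        for name, true in zip(model.descriptor_names, beta):
            err = abs(model.coefficients[name] - true)
            assert err <= 3 * model.coefficient_std_errors[name]

    def test_rank_deficiency_raises(self):
        x = np.arange(10.0)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(SingularityError):
            fit_mlr(X, x)


class TestInternalMetrics:
    def test_mean_prediction_gives_zero_r2(self):
        y = np.array([1.0, 2, 3, 4])
        model = MLRModel(intercept=y.mean(), coefficients={"x0": 0.0},
                         coefficient_std_errors={"x0": 0.0}, intercept_std_error=0.0,
                         n_train=4, training_mean_y=y.mean(),
                         training_variance=y.var())
        m = internal_metrics(model, y[:, None], y)
        assert m["r2_tr"] == pytest.approx(0.0)

    def test_six_point_worked_example(self):
        # spreadsheet-style oracle: closed-form simple regression formulas
        x = np.array([0.0, 1, 2, 3, 4, 5])
        y = np.array([1.2, 2.8, 5.1, 7.0, 8.9, 11.2])
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        slope = sxy / sxx
        intercept = y.mean() - slope * x.mean()
        yhat = intercept + slope * x
        rss = ((y - yhat) ** 2).sum()
        tss = ((y - y.mean()) ** 2).sum()
        model = fit_mlr(pd.DataFrame({"x": x}), y)
        m = internal_metrics(model, pd.DataFrame({"x": x}), y)
        assert model.coefficients["x"] == pytest.approx(slope)
        assert m["r2_tr"] == pytest.approx(1 - rss / tss)
        assert m["r2_adj"] == pytest.approx(1 - (1 - (1 - rss / tss)) * 5 / 4)
        assert m["rmse_tr"] == pytest.approx(np.sqrt(rss / 6))
        assert m["mae_tr"] == pytest.approx(np.abs(y - yhat).mean())
        syy = ((yhat - yhat.mean()) ** 2).sum()
        sxy2 = ((y - y.mean()) * (yhat - yhat.mean())).sum()
        assert m["ccc_tr"] == pytest.approx(
            2 * sxy2 / (tss + syy + 6 * (y.mean() - yhat.mean()) ** 2))

    def test_zero_variance_response_rejected(self):
        X = np.arange(8.0)[:, None]
        model = fit_mlr(X, np.arange(8.0))
        with pytest.raises(ValueError, match="zero-variance"):
            internal_metrics(model, X, np.ones(8))


class TestQ2LOO:
    def test_hat_shortcut_equals_explicit_refits(self):
        X, y, _ = _noisy(n=30, p=3, sd=0.5, seed=2)
        assert q2_loo(X, y)["q2_loo"] == pytest.approx(
            loo_q2_bruteforce(X, y), abs=1e-10)

    def test_noise_free_linear_data_scores_one(self):
        X, y, _ = _noisy(sd=0.0)
        assert q2_loo(X, y)["q2_loo"] == pytest.approx(1.0)

    def test_permuted_response_scores_at_or_below_zero(self):
        X, y, _ = _noisy(n=100, sd=0.2, seed=3)
        rng = np.random.default_rng(0)
        scores = [q2_loo(X, rng.permutation(y))["q2_loo"] for _ in range(20)]
        assert np.mean(scores) < 0.05
        assert max(scores) < 0.3

    def test_loo_predictions_match_refit_predictions(self):
        X, y, _ = _noisy(n=25, p=2, seed=4)
        preds = loo_predictions(X, y)
        Xm = X.to_numpy()
        for i in (0, 7, 24):
            mask = np.ones(len(y), dtype=bool)
            mask[i] = False
            m = fit_mlr(Xm[mask], y[mask])
            assert preds[i] == pytest.approx(m.predict(Xm[[i]])[0], abs=1e-10)


class TestQ2LMO:
    def test_noise_free_data_scores_one(self):
        X, y, _ = _noisy(sd=0.0)
        assert q2_lmo(X, y, repeats=30, seed=0) == pytest.approx(1.0)

    def test_single_element_folds_reduce_to_loo(self):
        X, y, _ = _noisy(n=40, sd=0.4, seed=5)
        groups = [[i] for i in range(len(y))]
        assert q2_lmo(X, y, groups=groups) == pytest.approx(
            q2_loo(X, y)["q2_loo"], abs=1e-10)

    def test_close_to_loo_for_well_conditioned_data(self):
        X, y, _ = _noisy(n=150, sd=0.3, seed=6)
        assert abs(q2_lmo(X, y, repeats=300, seed=1)
                   - q2_loo(X, y)["q2_loo"]) < 0.05


class TestYScrambling:
    def test_predictive_data_scores_near_zero(self):
        X, y, _ = _noisy(n=200, sd=0.2, seed=7)
        assert y_scrambling(X, y, n_permutations=100, seed=0) < 0.05

    def test_overfit_regime_scores_high(self):
        X, y, _ = _noisy(n=8, p=5, sd=0.2, seed=8)
        assert y_scrambling(X, y, n_permutations=100, seed=0) > 0.3

    def test_identity_permuter_reproduces_training_r2(self):
        X, y, _ = _noisy(seed=9)
        model = fit_mlr(X, y)
        r2 = internal_metrics(model, X, y)["r2_tr"]
        same = y_scrambling(X, y, n_permutations=5, seed=0,
                            permuter=lambda rng, yy: yy)
        assert same == pytest.approx(r2, abs=1e-12)


class TestExternalMetrics:
    def test_perfect_predictions(self):
        X, y, _ = _noisy(sd=0.0, seed=10)
        model = fit_mlr(X, y)
        m = external_metrics(model, X, y)
        for key in ("q2_f1", "q2_f2", "q2_f3", "ccc_ex", "r2_ex"):
            assert m[key] == pytest.approx(1.0)

    def test_f1_equals_f2_when_means_agree(self):
        X, y, _ = _noisy(n=80, sd=0.3, seed=11)
        model = fit_mlr(X, y)
        m = external_metrics(model, X, y, training_mean_y=float(np.mean(y)))
        assert m["q2_f1"] == pytest.approx(m["q2_f2"], abs=1e-12)

    def test_eight_point_worked_example(self):
        model = MLRModel(intercept=1.0, coefficients={"x": 2.0},
                         coefficient_std_errors={"x": 0.0}, intercept_std_error=0.0,
                         n_train=10, training_mean_y=6.0, training_variance=4.0)
        X = pd.DataFrame({"x": [0.0, 1, 2, 3, 4, 5, 6, 7]})
        y = np.array([1.5, 2.5, 5.5, 7.0, 9.5, 10.5, 13.5, 14.5])
        m = external_metrics(model, X, y)
        yhat = 1 + 2 * X["x"].to_numpy()
        rss = ((yhat - y) ** 2).sum()          # seven errors of 0.5, one of 0
        assert rss == pytest.approx(1.75)
        assert m["q2_f1"] == pytest.approx(1 - 1.75 / ((y - 6.0) ** 2).sum())
        assert m["q2_f2"] == pytest.approx(1 - 1.75 / ((y - y.mean()) ** 2).sum())
        assert m["q2_f3"] == pytest.approx(1 - (1.75 / 8) / 4.0)
        assert m["rmse_ex"] == pytest.approx(np.sqrt(1.75 / 8))

    def test_empty_external_set_rejected(self):
        X, y, _ = _noisy(seed=12)
        model = fit_mlr(X, y)
        with pytest.raises(ValueError, match="empty"):
            external_metrics(model, X.iloc[:0], y[:0])


class TestCCC:
    def test_bounded_by_pearson_on_random_pairs(self):
        rng = np.random.default_rng(13)
        for _ in range(20):
            x = rng.normal(size=50)
            y = 0.5 * x + rng.normal(scale=rng.uniform(0.1, 2), size=50) \
                + rng.uniform(-2, 2)
            assert abs(ccc(x, y)) <= abs(np.corrcoef(x, y)[0, 1]) + 1e-12


class TestApplicabilityDomain:
    def test_published_cutoff_shape(self):
        assert leverage_cutoff(6, 1024) == pytest.approx(0.021, abs=5e-4)

    def test_training_leverages_average_hat_trace(self):
        X, y, _ = _noisy(n=50, p=4, seed=14)
        model = fit_mlr(X, y)
        resid = y - model.predict(X)
        ad = applicability_domain(model, X, residuals=resid)
        assert ad.leverages.mean() == pytest.approx((4 + 1) / 50)
        assert np.all((ad.leverages >= 0) & (ad.leverages <= 1))

    def test_far_outside_point_exceeds_cutoff(self):
        X, y, _ = _noisy(n=60, p=2, seed=15)
        model = fit_mlr(X, y)
        outlier = pd.DataFrame({"x0": [40.0], "x1": [-40.0]})
        X_all = pd.concat([X, outlier], ignore_index=True)
        resid = np.append(y - model.predict(X), 0.0)
        ad = applicability_domain(model, X, X_all, resid,
                                  ids=[str(i) for i in range(len(X_all))])
        assert ad.leverages[-1] > ad.h_star
        assert str(len(X)) in ad.outside_domain_ids

    def test_large_standardized_residual_flagged(self):
        X, y, _ = _noisy(n=60, p=2, sd=0.1, seed=16)
        y = y.copy()
        y[10] += 5.0
        model = fit_mlr(X, y)
        resid = y - model.predict(X)
        ad = applicability_domain(model, X, residuals=resid)
        assert "10" in ad.outside_domain_ids


class TestCriteria:
    def test_published_battery_passes_everything(self):
        checks = criteria_check(ValidationReport(metrics=dict(TABLE2)))
        assert checks["overall"]
        assert all(checks.values())

    def test_weak_training_fit_fails_first_criterion(self):
        m = dict(TABLE2, r2_tr=0.55)
        checks = criteria_check(ValidationReport(metrics=m))
        assert not checks["r2_tr >= 0.6"] and not checks["overall"]

    def test_equal_rmse_fails_strict_inequality(self):
        m = dict(TABLE2, rmse_cv=TABLE2["rmse_tr"])
        checks = criteria_check(ValidationReport(metrics=m))
        assert not checks["rmse_tr < rmse_cv"]

    def test_missing_metric_raises(self):
        incomplete = {k: v for k, v in TABLE2.items() if k != "q2_lmo"}
        with pytest.raises(IncompleteReportError):
            criteria_check(ValidationReport(metrics=incomplete))


class TestRandomSplit:
    def test_eighty_twenty_of_ten(self):
        s = random_split(list(range(10)), 0.8, seed=0)
        assert len(s.train_ids) == 8 and len(s.test_ids) == 2

    def test_reproducible_for_fixed_seed(self):
        a = random_split(list(range(100)), seed=4)
        b = random_split(list(range(100)), seed=4)
        assert a == b

    def test_explicit_size_override(self):
        s = random_split([f"m{i}" for i in range(1278)], sizes=(1024, 254), seed=1)
        assert len(s.train_ids) == 1024 and len(s.test_ids) == 254
        assert set(s.train_ids).isdisjoint(s.test_ids)

    def test_mismatched_sizes_rejected(self):
        with pytest.raises(ValueError):
            random_split(list(range(20)), sizes=(15, 4), seed=0)


class TestValidateModel:
    def test_full_battery_on_clean_synthetic_data(self):
        X, y, _ = _noisy(n=150, sd=0.3, seed=17)
        split = random_split(list(range(150)), 0.8, seed=0)
        tr, te = list(split.train_ids), list(split.test_ids)
        model, report, ad = validate_model(
            X.iloc[tr], y[tr], X.iloc[te], y[te], seed=0,
            lmo_repeats=100, n_scrambles=100)
        assert report.criteria_pass["overall"]
        assert ad.h_star == pytest.approx(leverage_cutoff(3, len(tr)))
        assert len(ad.leverages) == 150
        table = report.to_table()
        assert "Q2_LOO" in table and "CCC_ex" in table
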