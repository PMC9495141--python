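"""Regression, stepwise selection, correlations and yield definitions."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats
from sklearn.linear_model import LinearRegression
from sklearn.model_selection import KFold

import filletvol as fv
from filletvol.models import DegeneratePredictorError, cv_rmse


class TestFitSimple:
    def test_perfect_line(self):
        x = np.arange(10.0)
        fit = fv.fit_simple(x, 2 * x + 1)
        assert fit.slopes[0] == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.rmse_resub == pytest.approx(0.0, abs=1e-9)

    def test_constant_predictor_rejected(self):
        with pytest.raises(DegeneratePredictorError):
            fv.fit_simple(np.ones(10), np.arange(10.0))

    def test_r2_equals_squared_pearson(self, rng):
        x = rng.normal(size=200)
        y = 3 * x + rng.normal(size=200)
        fit = fv.fit_simple(x, y)
        r = stats.pearsonr(x, y).statistic
        assert fit.r_squared == pytest.approx(r * r, rel=1e-10)

    def test_intercept_identity(self, rng):
        x = rng.uniform(10, 60, size=80)
        y = 0.13 + 1.47 * x + rng.normal(0, 3, size=80)
        fit = fv.fit_simple(x, y)
        assert fit.intercept == pytest.approx(
            y.mean() - fit.slopes[0] * x.mean(), rel=1e-9
        )

    def test_slope_recovery_single_replicate(self):
        # generating coefficients: the best single-span model of the study
        rng = np.random.default_rng(42)
        x = rng.uniform(17.3, 62.5, size=1000)
        y = 0.13 + 1.47 * x + rng.normal(0, 3, size=1000)
        fit = fv.fit_simple(x, y)
        se = 3.0 / (np.sqrt(1000) * x.std())
        assert abs(fit.slopes[0] - 1.47) < 1.96 * se * 1.5


class TestPredict:
    def test_regression_through_the_means(self):
        """The printed A2 model evaluated at the mean A2 returns the mean
        actual fillet volume (to printed rounding)."""
        fit = fv.RegressionFit(("A2",), -1.63, (13.79,), 0.82, 7.51, 44)
        assert round(fv.predict(fit, 3.68), 2) == 49.12

    def test_zero_slope_constant_model(self):
        fit = fv.RegressionFit(("x",), 5.0, (0.0,), 0.0, 1.0, 10)
        assert fv.predict(fit, 123.0) == 5.0

    def test_multivariable_prediction_at_training_means(self, rng):
        X = pd.DataFrame(rng.normal(size=(60, 3)), columns=list("abc"))
        y = rng.normal(size=60) + X["a"] * 2
        fit = fv.fit_multiple(X, y)
        at_means = fv.predict(fit, {c: X[c].mean() for c in X})
        assert at_means == pytest.approx(y.mean(), rel=1e-9)

    def test_missing_predictor_rejected(self):
        fit = fv.RegressionFit(("a", "b"), 0.0, (1.0, 1.0), 0.5, 1.0, 10)
        with pytest.raises(KeyError):
            fv.predict(fit, {"a": 1.0})


def sklearn_cv_rmse(X, y, folds):
    """Independent CV-RMSE oracle via scikit-learn."""
    n = len(y)
    sq = np.empty(n)
    for train, test in folds:
        model = LinearRegression().fit(X[train], y[train])
        sq[test] = (y[test] - model.predict(X[test])) ** 2
    return np.sqrt(sq.mean())


class TestStepwise:
    def test_single_candidate_equals_simple_fit(self, rng):
        x = rng.uniform(0, 10, size=50)
        y = 2 * x + rng.normal(size=50)
        model = fv.stepwise_forward_cv(pd.DataFrame({"x": x}), y, k=5, seed=1)
        simple = fv.fit_simple(x, y)
        assert model.selected == ("x",)
        assert model.fit.slopes[0] == pytest.approx(simple.slopes[0])
        assert model.fit.intercept == pytest.approx(simple.intercept)

    def test_planted_linear_candidate_enters_first(self, rng):
        n = 120
        signal = rng.uniform(0, 10, size=n)
        cands = pd.DataFrame(
            {
                "noise1": rng.normal(size=n),
                "signal": signal,
                "noise2": rng.normal(size=n),
            }
        )
        y = 4.0 * signal + 1.0
        model = fv.stepwise_forward_cv(cands, y, k=10, seed=2)
        assert model.selected[0] == "signal"

    def test_each_step_matches_exhaustive_search(self, rng):
        """Per-step brute force over all one-variable additions, scored by
        an independent scikit-learn CV-RMSE, confirms every greedy choice."""
        n, p = 90, 5
        X = pd.DataFrame(
            rng.normal(size=(n, p)), columns=[f"c{i}" for i in range(p)]
        )
        y = (
            1.5 * X["c1"].to_numpy()
            - 2.0 * X["c3"].to_numpy()
            + rng.normal(0, 0.8, size=n)
        )
        seed = 13
        model = fv.stepwise_forward_cv(X, y, k=10, seed=seed, entry_tol=1e-3)

        folds = list(
            KFold(n_splits=10, shuffle=True, random_state=seed).split(
                np.zeros(n)
            )
        )
        chosen: list[str] = []
        for accepted in model.selected:
            scores = {
                c: sklearn_cv_rmse(
                    X[chosen + [c]].to_numpy(), y, folds
                )
                for c in X.columns
                if c not in chosen
            }
            best = min(scores, key=lambda c: (scores[c], list(X.columns).index(c)))
            assert accepted == best
            chosen.append(accepted)

    def test_cv_trace_non_increasing(self, seed7_bundle):
        t = seed7_bundle.traits
        model = fv.stepwise_forward_cv(
            t[[f"V{i}" for i in range(1, 10)]],
            t["fillet_volume_cm3"].to_numpy(float),
            k=10,
            seed=7,
        )
        trace = (model.baseline_cv_rmse,) + model.cv_trace
        assert all(b < a for a, b in zip(trace, trace[1:]))
        assert len(set(model.selected)) == len(model.selected)

    def test_k_larger_than_n_rejected(self, rng):
        X = pd.DataFrame({"x": rng.normal(size=5)})
        with pytest.raises(ValueError):
            fv.stepwise_forward_cv(X, np.arange(5.0), k=10, seed=0)


class TestCorrelations:
    def test_identity_is_maximally_significant(self, rng):
        x = rng.normal(size=44)
        res = fv.pearson_with_significance(x, x)
        assert res.r == pytest.approx(1.0)
        assert res.significance == "p<0.01"

    @pytest.mark.parametrize(
        "r,expected",
        [(0.30, "p<0.05"), (0.29, "ns"), (0.40, "p<0.01")],
    )
    def test_printed_band_examples_at_n44(self, r, expected):
        _, cls = fv.classify_correlation(r, 44)
        assert cls == expected

    def test_critical_r_at_n44(self):
        assert fv.critical_r(44, 0.05) == pytest.approx(0.297, abs=5e-4)
        # the exact p<0.01 bound; the published table prints 0.388
        assert fv.critical_r(44, 0.01) == pytest.approx(0.384, abs=5e-4)

    @settings(derandomize=True, max_examples=100)
    @given(
        r=st.floats(-0.99, 0.99),
        n=st.integers(5, 200),
    )
    def test_banding_matches_direct_p_value(self, r, n):
        p, cls = fv.classify_correlation(r, n)
        t = r * np.sqrt((n - 2) / (1 - r * r))
        p_direct = 2 * stats.t.sf(abs(t), df=n - 2)
        assert p == pytest.approx(p_direct, rel=1e-12)
        assert cls == (
            "p<0.01" if p_direct < 0.01
            else "p<0.05" if p_direct < 0.05
            else "ns"
        )

    def test_constant_vector_rejected(self):
        with pytest.raises(DegeneratePredictorError):
            fv.pearson_with_significance(np.ones(10), np.arange(10.0))


class TestYields:
    def test_zero_numerator(self):
        assert fv.fillet_yield(0.0, 300.0) == 0.0

    def test_equal_weights(self):
        assert fv.fillet_yield(250.0, 250.0) == 100.0

    def test_reference_mean_weights(self):
        # ratio of printed means; intentionally differs from the printed
        # mean yield 16.32, which is a mean of per-fish ratios
        assert fv.fillet_yield(49.31, 298.54) == pytest.approx(16.52, abs=0.005)

    def test_nonpositive_body_weight_rejected(self):
        with pytest.raises(ValueError):
            fv.fillet_yield(10.0, 0.0)

    def test_yield_v15_reference_arithmetic(self):
        fit = fv.RegressionFit(("V1-5",), 0.13, (1.47,), 0.97, 3.08, 44)
        out = fv.fillet_yield_v15(fit, 33.39, 298.54)
        assert out == pytest.approx(16.485, abs=0.005)

    def test_yield_v15_null_model(self):
        fit = fv.RegressionFit(("V1-5",), 0.0, (0.0,), 0.0, 1.0, 44)
        assert fv.fillet_yield_v15(fit, 33.39, 298.54) == 0.0


def test_cv_rmse_baseline_is_response_spread(rng):
    """Intercept-only CV-RMSE approximates the sd of the response."""
    y = rng.normal(10, 2, size=500)
    assert cv_rmse(None, y, k=10, seed=0) == pytest.approx(y.std(), rel=0.05)
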