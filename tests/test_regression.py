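"""OLS, leave-one-out statistics, collinearity filter and stepwise search."""

import numpy as np
import pytest

from qsabr import (
    SingularDesignError,
    UndefinedLOOError,
    fit_ols,
    loo_stats,
    r2_pred,
    remove_collinear,
    stepwise_select,
)


def brute_force_press(X, y):
    """Independent LOO oracle: refit with plain lstsq, leaving each row out."""
    X = np.atleast_2d(np.asarray(X, float))
    y = np.asarray(y, float).ravel()
    n = X.shape[0]
    press = 0.0
    for i in range(n):
        mask = np.arange(n) != i
        Z = np.hstack([np.ones((n - 1, 1)), X[mask]])
        beta, *_ = np.linalg.lstsq(Z, y[mask], rcond=None)
        pred = np.concatenate([[1.0], X[i]]) @ beta
        press += (y[i] - pred) ** 2
    return press


class TestFitOLS:
    def test_perfect_linear_fit(self):
        x = np.arange(1.0, 9.0)[:, None]
        model = fit_ols(x, 2.0 * x.ravel(), ["x"])
        assert model.coef["x"] == pytest.approx(2.0, abs=1e-10)
        assert model.intercept == pytest.approx(0.0, abs=1e-10)
        assert model.r2 == pytest.approx(1.0)
        assert model.se_reg == pytest.approx(0.0, abs=1e-8)
        assert model.press == pytest.approx(0.0, abs=1e-12)
        assert model.q2_loo == pytest.approx(1.0)

    def test_pure_noise_coefficient_coverage(self):
        """Independent noise: slope within 3 SE of zero almost always."""
        hits = 0
        n_rep = 1000
        for seed in range(n_rep):
            rng = np.random.default_rng(seed)
            x = rng.normal(size=(50, 1))
            y = rng.normal(size=50)
            m = fit_ols(x, y, ["x"], compute_loo=False)
            if abs(m.coef["x"]) <= 3.0 * m.coef_se["x"]:
                hits += 1
            assert abs(m.r2) < 0.5
        assert hits / n_rep >= 0.99

    def test_duplicated_column_is_singular(self, rng):
        x = rng.normal(size=(20, 1))
        X = np.hstack([x, x])
        with pytest.raises(SingularDesignError, match="b"):
            fit_ols(X, rng.normal(size=20), ["a", "b"])

    def test_too_few_observations(self, rng):
        with pytest.raises(ValueError):
            fit_ols(rng.normal(size=(3, 3)), rng.normal(size=3), list("abc"))

    def test_column_order_invariance(self, rng):
        X = rng.normal(size=(30, 3))
        y = X @ [1.0, -2.0, 0.5] + rng.normal(size=30)
        m1 = fit_ols(X, y, ["a", "b", "c"])
        m2 = fit_ols(X[:, ::-1], y, ["c", "b", "a"])
        for name in "abc":
            assert m1.coef[name] == pytest.approx(m2.coef[name], rel=1e-10)
        assert m1.r2 == pytest.approx(m2.r2, rel=1e-12)


class TestLOO:
    def test_closed_form_equals_brute_force(self):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            n = int(rng.integers(6, 13))
            p = int(rng.integers(1, min(5, n - 2)))
            X = rng.normal(size=(n, p))
            y = X @ rng.normal(size=p) + rng.normal(size=n)
            model = fit_ols(X, y, compute_loo=False)
            press, q2 = loo_stats(model, X, y)
            assert press == pytest.approx(brute_force_press(X, y), rel=1e-8)
            tss = np.sum((y - y.mean()) ** 2)
            assert q2 == pytest.approx(1.0 - press / tss, rel=1e-12)

    def test_q2_never_exceeds_r2(self, rng):
        for _ in range(30):
            n = int(rng.integers(8, 40))
            p = int(rng.integers(1, 5))
            X = rng.normal(size=(n, p))
            y = X @ rng.normal(size=p) + rng.normal(size=n)
            m = fit_ols(X, y)
            assert m.q2_loo <= m.r2 + 1e-12

    def test_unit_leverage_is_undefined(self):
        # one unique x value plus replicates: the unique point has h = 1
        X = np.array([[1.0]] * 6 + [[5.0]])
        y = np.array([2.0, 2.1, 1.9, 2.0, 2.2, 1.8, 9.0])
        model = fit_ols(X, y, compute_loo=False)
        with pytest.raises(UndefinedLOOError, match="6"):
            loo_stats(model, X, y)


class TestR2Pred:
    def test_exact_predictions_score_one(self, rng):
        X = rng.normal(size=(20, 2))
        y = X @ [1.0, 2.0] + 3.0
        m = fit_ols(X, y)
        assert r2_pred(m, X, y) == pytest.approx(1.0)

    def test_mean_model_on_symmetric_test_scores_zero(self):
        X = np.arange(10.0)[:, None]
        y = np.full(10, 7.0) + np.array([-1, 1, -1, 1, -1, 1, -1, 1, -1, 1]) * 0.5
        m = fit_ols(X, y, compute_loo=False)
        # force a constant model predicting the training mean
        m.coef["x0"] = 0.0
        m.intercept = m.y_train_mean
        y_test = np.array([m.y_train_mean - 2.0, m.y_train_mean + 2.0])
        assert r2_pred(m, np.array([[0.0], [1.0]]), y_test) == pytest.approx(0.0)

    def test_worked_four_point_example(self):
        X = np.array([[1.0], [2.0], [3.0]])
        y = np.array([2.0, 4.0, 6.0])
        m = fit_ols(X, y, ["x"], compute_loo=False)  # exact: y = 2x, mean 4
        X_test = np.array([[1.5], [2.5], [4.0], [5.0]])
        y_test = np.array([3.5, 4.5, 8.5, 9.0])
        preds = [2.0 * 1.5, 2.0 * 2.5, 2.0 * 4.0, 2.0 * 5.0]
        num = sum((yt - pr) ** 2 for yt, pr in zip(y_test, preds))
        den = sum((yt - 4.0) ** 2 for yt in y_test)
        assert r2_pred(m, X_test, y_test) == pytest.approx(1.0 - num / den, rel=1e-12)

    def test_degenerate_test_sets_rejected(self, rng):
        X = rng.normal(size=(10, 1))
        y = X.ravel() + rng.normal(size=10)
        m = fit_ols(X, y)
        with pytest.raises(ValueError, match="empty"):
            r2_pred(m, np.empty((0, 1)), np.empty(0))
        with pytest.raises(ValueError):
            r2_pred(m, np.array([[0.0]]), np.array([m.y_train_mean]))


class TestRemoveCollinear:
    def test_exact_duplicate_dropped(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([x, x, rng.normal(size=20)])
        Xr, kept, dropped = remove_collinear(X, ["a", "b", "c"], threshold=1.0)
        assert kept == ("a", "c")
        assert dropped[0][:2] == ("b", "a")

    def test_threshold_one_keeps_non_duplicates(self, rng):
        x = rng.normal(size=50)
        X = np.column_stack([x, x + 0.01 * rng.normal(size=50)])
        _, kept, dropped = remove_collinear(X, ["a", "b"], threshold=1.0)
        assert kept == ("a", "b") and not dropped

    def test_three_mutually_correlated_columns(self):
        rng = np.random.default_rng(5)
        base = rng.normal(size=2000)
        cols = [base + 0.09 * rng.normal(size=2000) for _ in range(3)]
        X = np.column_stack(cols)
        corr = np.corrcoef(X.T)
        assert (np.abs(corr[np.triu_indices(3, 1)]) > 0.99).all()
        Xr, kept, dropped = remove_collinear(X, ["a", "b", "c"], threshold=0.99)
        # greedy later-column rule: only the first survives
        assert kept == ("a",)
        assert {d[0] for d in dropped} == {"b", "c"}
        # every retained pair satisfies the threshold (trivially here)
        assert Xr.shape[1] == 1

    def test_constant_column_dropped_with_warning(self, rng):
        X = np.column_stack([np.full(15, 3.0), rng.normal(size=15)])
        with pytest.warns(UserWarning, match="constant"):
            _, kept, dropped = remove_collinear(X, ["const", "x"])
        assert kept == ("x",)
        assert dropped[0][0] == "const"


class TestStepwise:
    def test_recovers_single_true_descriptor(self):
        recovered = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 6))
            y = 3.0 * X[:, 2] + 1e-9 * rng.normal(size=40)
            model, trace = stepwise_select(X, y, list("abcdef"))
            if model.names == ("c",):
                recovered += 1
        assert recovered == 100

    def test_pure_noise_yields_intercept_only(self, rng):
        X = rng.normal(size=(40, 5))
        y = rng.normal(size=40)
        model, trace = stepwise_select(X, y, alpha_enter=1e-12, alpha_remove=1e-12)
        assert model.names == ()
        assert model.intercept == pytest.approx(y.mean())
        assert not trace.steps

    def test_recovers_two_descriptor_support_with_noise(self):
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(55, 6))
            signal = 2.0 * X[:, 1] + 1.5 * X[:, 4]
            y = signal + 0.5 * signal.std() * rng.normal(size=55)
            model, trace = stepwise_select(X, y, list("abcdef"))
            added = {s.name for s in trace.steps if s.action == "add"}
            if {"b", "e"} <= added and {"b", "e"} <= set(model.names):
                hits += 1
        assert hits >= 95

    def test_final_model_has_no_removable_variable(self, rng):
        X = rng.normal(size=(60, 8))
        y = X[:, 0] + 0.5 * X[:, 3] + rng.normal(size=60)
        model, _ = stepwise_select(X, y, alpha_enter=0.25, alpha_remove=0.25)
        # every included variable must survive its own partial-F test
        from scipy import stats as sps

        names = [f"x{i}" for i in range(8)]
        idx = [names.index(n) for n in model.names]
        n, k = 60, len(idx)
        Z = np.hstack([np.ones((n, 1)), X[:, idx]])
        beta, *_ = np.linalg.lstsq(Z, y, rcond=None)
        rss_full = np.sum((y - Z @ beta) ** 2)
        for j in range(k):
            keep = [i for i in range(k) if i != j]
            Zr = Z[:, [0] + [i + 1 for i in keep]]
            br, *_ = np.linalg.lstsq(Zr, y, rcond=None)
            rss_red = np.sum((y - Zr @ br) ** 2)
            F = (rss_red - rss_full) / (rss_full / (n - k - 1))
            p = sps.f.sf(F, 1, n - k - 1)
            assert p <= 0.25 + 1e-12

    def test_skips_linearly_dependent_candidates(self, rng):
        x = rng.normal(size=(40, 2))
        X = np.column_stack([x[:, 0], x[:, 1], x[:, 0] - x[:, 1]])
        y = 2.0 * X[:, 0] - 1.0 * X[:, 1] + 0.1 * rng.normal(size=40)
        model, _ = stepwise_select(X, y, ["a", "b", "a_minus_b"])
        assert len(model.names) <= 2  # the third column can never join both others
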