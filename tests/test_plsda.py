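"""NIPALS PLS-DA core: fit/predict, complexity selection, VIP, TP and SR."""

import numpy as np
import pytest
from sklearn.cross_decomposition import PLSRegression

from metabopls import (
    SyntheticSpec,
    fit_plsda,
    generate_cohort,
    predict,
    select_complexity_loo,
    selectivity_ratio,
    target_projection,
    vip_scores,
)
from metabopls.plsda import (
    RankDeficiencyError,
    _cumulative_regression_vectors,
    _nipals_pls1,
)
from metabopls.preprocess import fit_scaling, apply_scaling


def _random_scaled_problem(rng, n=None, p=None):
    n = n or int(rng.integers(8, 40))
    p = p or int(rng.integers(2, 25))
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0, ddof=1)
    y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
    y[:2] = [1.0, -1.0]
    return X, y


class TestFit:
    def test_one_step_nipals_hand_computation(self):
        """A=1 regression vector equals the explicit single-step formulas.

        On a printed 4 x 2 fixture: w = X'y/||X'y||, t = Xw, p = X't/t't,
        q = y't/t't and b = w q/(p'w).
        """
        X = np.array([[1.0, 2.0], [-1.0, 0.5], [2.0, -1.0], [-2.0, -1.5]])
        y = np.array([1.0, 1.0, -1.0, -1.0])
        w = X.T @ y
        w = w / np.linalg.norm(w)
        t = X @ w
        p_load = X.T @ t / (t @ t)
        q = y @ t / (t @ t)
        b_hand = w * q / (p_load @ w)

        model = fit_plsda(X, y, 1)
        assert np.allclose(model.b, b_hand, atol=1e-12)
        assert np.allclose(model.T[:, 0], t)
        assert model.q[0] == pytest.approx(q)

    def test_duplicated_columns_get_equal_coefficients(self, rng):
        X, y = _random_scaled_problem(rng, n=20, p=6)
        X[:, 3] = X[:, 1]
        model = fit_plsda(X, y, 2)
        assert model.b[1] == pytest.approx(model.b[3], abs=1e-8)

    def test_perfectly_ordered_univariate_separates_training(self):
        X = np.linspace(-1, 1, 10).reshape(-1, 1)
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        model = fit_plsda(X, y, 1)
        scores, labels = predict(model, X)
        assert np.array_equal(labels, y)

    def test_matches_sklearn_pls_regression(self, rng):
        """Independent cross-check of the NIPALS regression vector."""
        for _ in range(5):
            X, y = _random_scaled_problem(rng, n=30, p=10)
            y = y - y.mean()  # sklearn centers y; align the codings
            for A in (1, 2, 3):
                model = fit_plsda(X, y, A)
                sk = PLSRegression(n_components=A, scale=False).fit(X, y)
                assert np.allclose(model.b, sk.coef_.ravel(), atol=1e-8)

    def test_scores_orthogonal_and_b_reproduces_tq_path(self, rng):
        for _ in range(10):
            X, y = _random_scaled_problem(rng)
            A = int(rng.integers(1, min(4, X.shape[1]) + 1))
            model = fit_plsda(X, y, A)
            G = model.T.T @ model.T
            off = G - np.diag(np.diag(G))
            assert np.all(np.abs(off) <= 1e-8 * np.abs(np.diag(G)).max())
            assert np.allclose(X @ model.b, model.T @ model.q, atol=1e-8)

    def test_single_class_and_excess_components_rejected(self, rng):
        X = rng.standard_normal((6, 3))
        with pytest.raises(ValueError, match="both classes"):
            fit_plsda(X, np.ones(6), 1)
        with pytest.raises(RankDeficiencyError):
            fit_plsda(X, np.array([1, -1, 1, -1, 1, -1.0]), 5)


class TestPredict:
    def test_training_predictions_reproduced(self, rng):
        X, y = _random_scaled_problem(rng, n=15, p=5)
        model = fit_plsda(X, y, 2)
        s1, _ = predict(model, X)
        assert np.allclose(s1, X @ model.b)

    def test_zero_score_goes_to_negative_class(self):
        X = np.array([[1.0], [-1.0], [0.5], [-0.5]])
        y = np.array([1.0, -1.0, 1.0, -1.0])
        model = fit_plsda(X, y, 1, y_coding={"OSAS": 1, "COPD": -1})
        _, labels = predict(model, np.array([[0.0]]))
        assert labels[0] == "COPD"

    def test_duplicated_rows_score_identically(self, rng):
        X, y = _random_scaled_problem(rng, n=12, p=4)
        model = fit_plsda(X, y, 1)
        s, _ = predict(model, np.vstack([X[3], X[3]]))
        assert s[0] == s[1]

    def test_variable_mismatch_rejected(self, rng):
        X, y = _random_scaled_problem(rng, n=12, p=4)
        model = fit_plsda(X, y, 1)
        with pytest.raises(ValueError, match="mismatch"):
            predict(model, np.ones((2, 7)))

    def test_scaling_applied_internally(self, default_cohort):
        params = fit_scaling(default_cohort.values, default_cohort.variable_names)
        Xs = apply_scaling(default_cohort.values, params)
        y = np.where(default_cohort.group_labels == "OSAS", 1.0, -1.0)
        model = fit_plsda(Xs, y, 2, scaling=params)
        s_raw, _ = predict(model, default_cohort.values)
        assert np.allclose(s_raw, Xs @ model.b)


class TestComplexitySelection:
    def test_a_max_one_returns_one(self, rng):
        X, y = _random_scaled_problem(rng, n=12, p=4)
        assert select_complexity_loo(X, y, 1) == 1

    def test_matches_explicit_per_fold_refit(self, rng):
        """The batched LOO equals refitting NIPALS on every explicit fold."""
        for _ in range(8):
            n, p = int(rng.integers(10, 30)), int(rng.integers(3, 15))
            X = np.exp(rng.standard_normal((n, p)))
            y = np.where(rng.random(n) < 0.5, 1.0, -1.0)
            y[:2] = [1.0, -1.0]
            A_max = 4
            A_eff = min(A_max, n - 1, p)
            errors = np.zeros(A_eff)
            for i in range(n):
                mask = np.ones(n, bool)
                mask[i] = False
                Xt = X[mask]
                m, s = Xt.mean(0), Xt.std(0, ddof=1)
                s[s <= 0] = 1.0
                W, P, _T, q = _nipals_pls1((Xt - m) / s, y[mask], A_eff)
                B = _cumulative_regression_vectors(W, P, q, A_eff)
                pred = np.where(((X[i] - m) / s) @ B > 0, 1.0, -1.0)
                errors += pred != y[i]
            expected = int(np.argmin(errors)) + 1
            assert select_complexity_loo(X, y, A_max) == expected

    def test_single_informative_variable_selects_one_component(self):
        """With one dominant variable plus noise, LOO should pick A = 1.

        Parsimony (ties to the smaller model) wins when the one-component
        model already classifies every fold, so the planted variable must
        dominate the noise loadings of the first weight vector.
        """
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            n = 100
            y = np.repeat([1.0, -1.0], n // 2)
            X = rng.standard_normal((n, 3))
            X[:, 0] += 8.0 * y
            hits += select_complexity_loo(X, y, 4) == 1
        assert hits >= 95

    def test_pure_noise_loo_error_near_half(self):
        rates = []
        for seed in range(100):
            rng = np.random.default_rng(1000 + seed)
            n = 24
            y = np.repeat([1.0, -1.0], n // 2)
            X = rng.standard_normal((n, 8))
            A = select_complexity_loo(X, y, 3)
            # recompute the LOO error of the selected complexity explicitly
            errs = 0
            for i in range(n):
                mask = np.ones(n, bool)
                mask[i] = False
                Xt = X[mask]
                m, s = Xt.mean(0), Xt.std(0, ddof=1)
                model = fit_plsda((Xt - m) / s, y[mask], A)
                errs += (1.0 if ((X[i] - m) / s) @ model.b > 0 else -1.0) != y[i]
            rates.append(errs / n)
        assert abs(np.mean(rates) - 0.5) < 0.15


class TestVIP:
    def test_single_variable_vip_is_one(self):
        X = np.linspace(-1, 1, 8).reshape(-1, 1)
        y = np.where(X[:, 0] > 0, 1.0, -1.0)
        assert vip_scores(fit_plsda(X, y, 1))[0] == pytest.approx(1.0)

    def test_one_component_concentrated_weight(self):
        """A=1 with w = (1, 0) gives VIPs (sqrt(2), 0) by the formula."""
        y = np.array([1.0, 1.0, -1.0, -1.0])
        X = np.column_stack([y * 2.0, np.array([1.0, -1.0, 1.0, -1.0])])
        model = fit_plsda(X, y, 1)
        assert np.allclose(model.W[:, 0], [1.0, 0.0], atol=1e-12)
        assert np.allclose(vip_scores(model), [np.sqrt(2.0), 0.0], atol=1e-10)

    def test_mean_squared_vip_is_unity(self, rng):
        for _ in range(20):
            X, y = _random_scaled_problem(rng)
            A = int(rng.integers(1, min(4, X.shape[1]) + 1))
            vip = vip_scores(fit_plsda(X, y, A))
            assert np.mean(vip**2) == pytest.approx(1.0, abs=1e-8)
            assert np.all(vip >= 0)


class TestTargetProjectionAndSR:
    def test_one_component_identity(self, rng):
        X, y = _random_scaled_problem(rng, n=20, p=6)
        model = fit_plsda(X, y, 1)
        tp = target_projection(model, X)
        ratio = tp.t_tp / model.T[:, 0]
        assert np.allclose(ratio, ratio[0])
        # SR from TP equals the single-component explained/residual ratio
        t1 = model.T[:, 0]
        p1 = X.T @ t1 / (t1 @ t1)
        explained = (t1 @ t1) * p1**2
        total = (X**2).sum(axis=0)
        sr_direct = explained / (total - explained)
        assert np.allclose(selectivity_ratio(tp), sr_direct, rtol=1e-8)

    def test_explained_plus_residual_equals_total(self, rng):
        for _ in range(10):
            X, y = _random_scaled_problem(rng)
            A = int(rng.integers(1, min(4, X.shape[1]) + 1))
            model = fit_plsda(X, y, A)
            tp = target_projection(model, X)
            assert np.allclose(
                tp.explained + tp.residual, tp.total, rtol=1e-8, atol=1e-12
            )

    def test_sr_matches_regression_oracle_on_toy_fixture(self):
        """SR equals explained/residual from regressing each variable on t_TP."""
        X = np.array(
            [
                [1.2, -0.5, 0.3],
                [-0.7, 0.9, -1.1],
                [0.4, -1.3, 0.8],
                [-1.5, 0.6, 0.2],
                [0.6, 0.3, -0.2],
            ]
        )
        X = (X - X.mean(0)) / X.std(0, ddof=1)
        y = np.array([1.0, -1.0, 1.0, -1.0, 1.0])
        model = fit_plsda(X, y, 2)
        tp = target_projection(model, X)
        sr = selectivity_ratio(tp)
        for j in range(3):
            slope = np.linalg.lstsq(
                tp.t_tp.reshape(-1, 1), X[:, j], rcond=None
            )[0][0]
            fitted = slope * tp.t_tp
            ess = float(fitted @ fitted)
            rss = float(((X[:, j] - fitted) ** 2).sum())
            assert sr[j] == pytest.approx(ess / rss, rel=1e-8)

    def test_variable_uncorrelated_with_target_has_zero_explained(self):
        y = np.array([1.0, 1.0, -1.0, -1.0])
        X = np.column_stack([y, np.array([1.0, -1.0, 1.0, -1.0])])
        model = fit_plsda(X, y, 1)
        tp = target_projection(model, X)
        assert tp.explained[1] == pytest.approx(0.0, abs=1e-12)
        assert selectivity_ratio(tp)[1] == 0.0

    def test_fully_explained_variable_reported_infinite(self):
        y = np.array([1.0, 1.0, -1.0, -1.0])
        X = np.column_stack([y * 1.0, y * 2.0])
        model = fit_plsda(X, y, 1)
        sr = selectivity_ratio(target_projection(model, X))
        assert np.all(np.isinf(sr))

    def test_sr_ranking_matches_correlation_with_scores_at_a1(self, rng):
        for _ in range(5):
            X, y = _random_scaled_problem(rng, n=25, p=8)
            model = fit_plsda(X, y, 1)
            sr = selectivity_ratio(target_projection(model, X))
            r2 = np.array(
                [np.corrcoef(X[:, j], model.T[:, 0])[0, 1] ** 2 for j in range(8)]
            )
            assert np.array_equal(np.argsort(sr), np.argsort(r2))


class TestSerialization:
    def test_model_json_round_trip(self, tmp_path, rng):
        X, y = _random_scaled_problem(rng, n=15, p=5)
        params = fit_scaling(X, [f"v{i}" for i in range(5)])
        model = fit_plsda(X, y, 2, scaling=params,
                          y_coding={"OSAS": 1, "COPD": -1},
                          variable_names=params.variable_names)
        path = tmp_path / "model.json"
        model.to_json(path)
        from metabopls.plsda import PLSDAModel

        back = PLSDAModel.from_json(path)
        assert back.n_components == 2
        assert np.allclose(back.b, model.b)
        assert np.allclose(back.W, model.W)
        assert back.y_coding == model.y_coding
        s1, l1 = predict(model, np.exp(X))
        s2, l2 = predict(back, np.exp(X))
        assert np.allclose(s1, s2)
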