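import numpy as np
import pytest
from scipy import optimize
from scipy.spatial.distance import cdist

import stackgs as sg


@pytest.fixture
def regression_fixture():
    rng = np.random.default_rng(5)
    n = 40
    X = rng.normal(size=(n, 6))
    beta = rng.normal(size=6)
    y = X @ beta + 0.2 * rng.normal(size=n)
    return X, y


class TestSVR:
    def test_constant_targets_fit_flat(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(25, 4))
        y = np.full(25, 3.7)
        m = sg.fit_svr(X, y, sg.SVRParams(C=1.0, epsilon=0.1, gamma=0.5))
        np.testing.assert_allclose(m.predict(X), 3.7, atol=0.1)

    def test_wide_tube_gives_near_constant_predictor(self, regression_fixture):
        X, y = regression_fixture
        eps = float(np.ptp(y))  # every residual fits inside the tube
        m = sg.fit_svr(X, y, sg.SVRParams(C=1e-3, epsilon=eps, gamma=0.5))
        pred = m.predict(X)
        assert np.ptp(pred) < 0.05 * np.ptp(y)

    def test_against_qp_dual_oracle(self):
        """Training predictions must match an independent solve of the SVR
        dual QP (in beta = alpha_hat - alpha, |beta| <= C, sum beta = 0)."""
        rng = np.random.default_rng(5)
        n = 30
        X = rng.normal(size=(n, 3))
        y = np.sin(X[:, 0]) + 0.5 * X[:, 1] + 0.1 * rng.normal(size=n)
        C, eps, gamma = 1.0, 0.1, 0.5
        K = np.exp(-gamma * cdist(X, X, "sqeuclidean"))

        res = optimize.minimize(
            lambda b: 0.5 * b @ K @ b - y @ b + eps * np.abs(b).sum(),
            np.zeros(n),
            jac=lambda b: K @ b - y + eps * np.sign(b),
            bounds=[(-C, C)] * n,
            constraints=[{"type": "eq", "fun": lambda b: b.sum()}],
            method="SLSQP",
            options={"maxiter": 2000, "ftol": 1e-14},
        )
        b = res.x
        f0 = K @ b
        margin = (np.abs(b) > 1e-6) & (np.abs(b) < C - 1e-6)
        assert margin.any()
        b0 = np.mean(y[margin] - f0[margin] - eps * np.sign(b[margin]))

        m = sg.fit_svr(X, y, sg.SVRParams(C=C, epsilon=eps, gamma=gamma))
        np.testing.assert_allclose(m.predict(X), f0 + b0, atol=1e-4)

    def test_nonfinite_features_rejected(self):
        X = np.array([[0.0, np.inf], [1.0, 2.0], [3.0, 4.0]])
        with pytest.raises(ValueError, match="non-finite"):
            sg.fit_svr(X, np.zeros(3))


class TestKRR:
    def test_zero_lambda_interpolates(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(20, 5))
        y = rng.normal(size=20)
        m = sg.fit_krr(X, y, sg.KRRParams(ridge_lambda=0.0, kernel="gaussian", gamma=0.3))
        np.testing.assert_allclose(m.predict(X), y, atol=1e-8)

    def test_identity_gram_halves_targets(self):
        # linear kernel with X = I gives K = I; (I + I)^{-1} y = y/2
        n = 8
        y = np.arange(1.0, n + 1)
        m = sg.fit_krr(np.eye(n), y, sg.KRRParams(ridge_lambda=1.0, kernel="linear"))
        np.testing.assert_allclose(m.predict(np.eye(n)), y / 2, atol=1e-10)

    def test_against_direct_inverse_oracle(self):
        rng = np.random.default_rng(2)
        n = 50
        X = rng.normal(size=(n, 4))
        y = rng.normal(size=n)
        lam, gamma = 0.5, 0.25
        K = np.exp(-gamma * cdist(X, X, "sqeuclidean"))
        expected = K @ np.linalg.inv(K + lam * np.eye(n)) @ y
        m = sg.fit_krr(X, y, sg.KRRParams(ridge_lambda=lam, kernel="gaussian", gamma=gamma))
        np.testing.assert_allclose(m.predict(X), expected, atol=1e-10)

    def test_precomputed_kernel(self):
        rng = np.random.default_rng(3)
        n = 30
        X = rng.normal(size=(n, 3))
        K = X @ X.T
        y = rng.normal(size=n)
        lam = 2.0
        m = sg.fit_krr(K, y, sg.KRRParams(ridge_lambda=lam, kernel="precomputed"))
        expected = K @ np.linalg.solve(K + lam * np.eye(n), y)
        np.testing.assert_allclose(m.predict(K), expected, atol=1e-10)


class TestENET:
    def test_alpha_zero_is_ols(self, regression_fixture):
        X, y = regression_fixture
        m = sg.fit_enet(X, y, sg.ENETParams(alpha=0.0, rho=0.5))
        Xd = np.column_stack([np.ones(len(y)), X])
        coef = np.linalg.lstsq(Xd, y, rcond=None)[0]
        np.testing.assert_allclose(m.predict(X), Xd @ coef, atol=1e-6)

    def test_huge_alpha_predicts_mean(self, regression_fixture):
        X, y = regression_fixture
        m = sg.fit_enet(X, y, sg.ENETParams(alpha=1e6, rho=0.5))
        np.testing.assert_allclose(m.predict(X), np.mean(y), atol=1e-8)

    def test_pure_ridge_matches_closed_form(self, regression_fixture):
        X, y = regression_fixture
        alpha = 0.3
        m = sg.fit_enet(X, y, sg.ENETParams(alpha=alpha, rho=0.0))
        # sklearn objective: (1/2n)||y - Xw||^2 + (alpha/2)||w||^2 with intercept
        n = len(y)
        Xc = X - X.mean(axis=0)
        yc = y - y.mean()
        w = np.linalg.solve(Xc.T @ Xc + n * alpha * np.eye(X.shape[1]), Xc.T @ yc)
        b = y.mean() - X.mean(axis=0) @ w
        np.testing.assert_allclose(m.predict(X), X @ w + b, atol=1e-8)


class TestGridSearch:
    def test_singleton_grid_returned(self, regression_fixture):
        X, y = regression_fixture
        p = sg.KRRParams(ridge_lambda=0.7, kernel="linear")
        best, table = sg.grid_search("krr", X, y, [p], seed=0)
        assert best == p
        assert len(table) == 1

    def test_selected_score_is_table_max(self, regression_fixture):
        X, y = regression_fixture
        grid = [sg.KRRParams(ridge_lambda=l, kernel="linear") for l in (1e-4, 0.1, 10.0, 1e4)]
        best, table = sg.grid_search("krr", X, y, grid, seed=1)
        assert table.loc[table["params"] == best, "score"].iloc[0] == table["score"].max()

    def test_deterministic_given_seed(self, regression_fixture):
        X, y = regression_fixture
        grid = [sg.SVRParams(C=c, epsilon=0.1, gamma=0.5) for c in (0.1, 1.0, 10.0)]
        b1, t1 = sg.grid_search("svr", X, y, grid, seed=9)
        b2, t2 = sg.grid_search("svr", X, y, grid, seed=9)
        assert b1 == b2
        np.testing.assert_array_equal(t1["score"], t2["score"])

    def test_failing_point_scored_minus_inf(self, regression_fixture):
        X, y = regression_fixture
        # an absurd ENET alpha shrinks everything to a constant predictor,
        # whose Pearson accuracy is undefined -> scored -inf, search continues
        grid = [sg.ENETParams(alpha=1e8, rho=0.5), sg.ENETParams(alpha=1e-3, rho=0.5)]
        with pytest.warns(RuntimeWarning):
            best, table = sg.grid_search("enet", X, y, grid, seed=0)
        assert best == grid[1]
        assert table["score"].iloc[0] == -np.inf

    def test_empty_grid_rejected(self, regression_fixture):
        X, y = regression_fixture
        with pytest.raises(ValueError, match="non-empty"):
            sg.grid_search("krr", X, y, [], seed=0)


def test_prediction_row_permutation_equivariance(regression_fixture):
    X, y = regression_fixture
    rng = np.random.default_rng(7)
    perm = rng.permutation(len(y))
    for kind, params in [
        ("svr", sg.SVRParams(C=1.0, epsilon=0.1, gamma=0.5)),
        ("krr", sg.KRRParams(ridge_lambda=0.5, kernel="gaussian", gamma=0.3)),
        ("enet", sg.ENETParams(alpha=1e-3, rho=0.5)),
    ]:
        m = sg.fit_learner(kind, X, y, params)
        mp = sg.fit_learner(kind, X[perm], y[perm], params)
        np.testing.assert_allclose(mp.predict(X), m.predict(X), atol=1e-6)
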