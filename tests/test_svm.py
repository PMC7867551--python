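"""Sparse L1/squared-hinge SVM: solver-oracle agreement, exact zeros,
sparsity behavior, estimator API."""

import numpy as np
import pytest
from scipy.optimize import minimize
from sklearn.base import clone
from sklearn.svm import LinearSVC

from sparsecoh._solver import objective_value
from sparsecoh.svm import (
    DegenerateLabelsError,
    SparseHingeSVM,
    train,
    weight_path,
    zero_cost_threshold,
)


def lbfgs_oracle(X, y, C):
    """Independent convex solver: smooth split-variable reformulation
    (w = u - v, u, v >= 0) of the L1/squared-hinge objective."""
    n, p = X.shape

    def fg(z):
        u, v = z[:p], z[p:]
        w = u - v
        marg = np.maximum(0.0, 1.0 - y * (X @ w))
        grad_h = -2.0 * C * (X.T @ (y * marg))
        return (
            u.sum() + v.sum() + C * marg @ marg,
            np.concatenate([1.0 + grad_h, 1.0 - grad_h]),
        )

    res = minimize(
        fg, np.zeros(2 * p), jac=True, method="L-BFGS-B",
        bounds=[(0.0, None)] * (2 * p),
        options=dict(maxiter=20_000, ftol=1e-16, gtol=1e-12),
    )
    return res.x[:p] - res.x[p:]


def random_problem(rng, n=None, p=None):
    n = n or int(rng.integers(4, 9))
    p = p or int(rng.integers(1, 7))
    X = rng.standard_normal((n, p))
    y = np.sign(rng.standard_normal(n))
    y[y == 0] = 1.0
    if len(np.unique(y)) < 2:
        y[0] *= -1.0
    return X, y


class TestSolver:
    def test_matches_lbfgs_oracle_on_random_problems(self):
        rng = np.random.default_rng(101)
        for _ in range(25):
            X, y = random_problem(rng)
            C = 10 ** rng.uniform(-2, 2.5)
            model = SparseHingeSVM(C=C, standardize=False,
                                   fit_intercept=False).fit(X, y)
            ours = objective_value(X, y, model.coef_, C)
            ref = objective_value(X, y, lbfgs_oracle(X, y, C), C)
            assert ours <= ref * (1 + 1e-6) + 1e-9
            assert abs(ours - ref) <= 1e-6 * max(1.0, abs(ref))

    def test_matches_liblinear_reference(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((30, 10))
        y = np.sign(rng.standard_normal(30))
        y[y == 0] = 1
        C = 5.0
        ours = SparseHingeSVM(C=C, standardize=False,
                              fit_intercept=False).fit(X, y)
        ref = LinearSVC(penalty="l1", loss="squared_hinge", dual=False,
                        C=C, fit_intercept=False, tol=1e-10,
                        max_iter=200_000).fit(X, y)
        f_ours = objective_value(X, y, ours.coef_, C)
        f_ref = objective_value(X, y, ref.coef_.ravel(), C)
        assert f_ours == pytest.approx(f_ref, rel=1e-6)

    def test_exact_zero_below_threshold(self):
        rng = np.random.default_rng(55)
        for _ in range(10):
            X, y = random_problem(rng, n=8, p=5)
            C0 = zero_cost_threshold(X, y)
            low = SparseHingeSVM(C=0.999 * C0, standardize=False,
                                 fit_intercept=False).fit(X, y)
            assert np.all(low.coef_ == 0.0)  # bit-exact zeros
            high = SparseHingeSVM(C=1.5 * C0, standardize=False,
                                  fit_intercept=False).fit(X, y)
            assert np.any(high.coef_ != 0.0)

    def test_separable_pair_in_one_dimension(self):
        X = np.array([[1.0], [-1.0]])
        y = np.array([1.0, -1.0])
        m = SparseHingeSVM(C=100.0, standardize=False,
                           fit_intercept=False).fit(X, y)
        assert m.coef_[0] > 0
        assert np.all(m.predict(X) == y)

    def test_objective_never_exceeds_zero_vector(self):
        rng = np.random.default_rng(77)
        for _ in range(10):
            X, y = random_problem(rng)
            C = 10 ** rng.uniform(-1, 2)
            m = SparseHingeSVM(C=C, standardize=False,
                               fit_intercept=False).fit(X, y)
            # F(0) = C * n since every margin is 1
            assert objective_value(X, y, m.coef_, C) <= C * len(y) + 1e-12

    def test_sparsity_nondecreasing_in_C_on_average(self):
        rng = np.random.default_rng(31)
        lo, hi = [], []
        for _ in range(20):
            X, y = random_problem(rng, n=12, p=8)
            mlo = SparseHingeSVM(C=0.3, standardize=False,
                                 fit_intercept=False).fit(X, y)
            mhi = SparseHingeSVM(C=30.0, standardize=False,
                                 fit_intercept=False).fit(X, y)
            lo.append(np.sum(mlo.coef_ != 0))
            hi.append(np.sum(mhi.coef_ != 0))
        assert np.mean(hi) >= np.mean(lo)

    def test_deterministic(self):
        rng = np.random.default_rng(13)
        X, y = random_problem(rng, n=20, p=10)
        a = SparseHingeSVM(C=3.0).fit(X, y)
        b = SparseHingeSVM(C=3.0).fit(X, y)
        np.testing.assert_array_equal(a.coef_, b.coef_)

    def test_weight_path_final_matches_direct_fit(self):
        rng = np.random.default_rng(17)
        X, y = random_problem(rng, n=15, p=6)
        grid = np.logspace(-1, 1, 5)
        W = weight_path(X, y, grid, standardize=False, fit_intercept=False)
        direct = SparseHingeSVM(C=grid[-1], standardize=False,
                                fit_intercept=False).fit(X, y)
        f_path = objective_value(X, y, W[-1], grid[-1])
        f_direct = objective_value(X, y, direct.coef_, grid[-1])
        assert f_path == pytest.approx(f_direct, rel=1e-6, abs=1e-9)


class TestEstimatorAPI:
    def test_score_is_linear(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((12, 4))
        y = np.sign(rng.standard_normal(12))
        y[y == 0] = 1
        m = SparseHingeSVM(C=10.0, standardize=False,
                           fit_intercept=False).fit(X, y)
        x = rng.standard_normal((1, 4))
        assert m.decision_function(2 * x)[0] == pytest.approx(
            2 * m.decision_function(x)[0]
        )

    def test_zero_model_scores_zero_and_predicts_negative(self):
        rng = np.random.default_rng(4)
        X = rng.standard_normal((10, 3))
        y = np.sign(rng.standard_normal(10))
        y[y == 0] = 1
        C0 = zero_cost_threshold(
            (X - X.mean(0)) / X.std(0), y
        )
        m = SparseHingeSVM(C=min(C0 * 0.5, 1e-4),
                           fit_intercept=False).fit(X, y)
        scores = m.decision_function(X)
        np.testing.assert_array_equal(scores, 0.0)
        assert np.all(m.predict(X) == m.classes_[0])  # tie -> negative

    def test_single_nonzero_weight_score(self):
        m = SparseHingeSVM(C=1.0, standardize=False, fit_intercept=False)
        m.coef_ = np.array([0.0, 2.0, 0.0])
        m.intercept_ = 0.0
        m.scale_mean_ = np.zeros(3)
        m.scale_std_ = np.ones(3)
        m.n_features_in_ = 3
        m.classes_ = np.array([-1.0, 1.0])
        m.feature_names_ = ("a", "b", "c")
        x = np.array([[9.0, 0.5, 9.0]])
        assert m.decision_function(x)[0] == pytest.approx(1.0)

    def test_nonzero_connections_sorted_by_magnitude(self):
        m = SparseHingeSVM()
        m.coef_ = np.array([0.0, -1.0, 3.0])
        m.intercept_ = 0.0
        m.scale_mean_ = np.zeros(3)
        m.scale_std_ = np.ones(3)
        m.n_features_in_ = 3
        m.classes_ = np.array(["sham", "active"])
        m.feature_names_ = ("pair1", "pair2", "pair3")
        nz = m.nonzero_connections()
        assert [t[0] for t in nz] == ["pair3", "pair2"]
        assert nz[0][2] == "increase" and nz[1][2] == "decrease"

    def test_single_class_raises(self):
        X = np.zeros((4, 2))
        y = np.ones(4)
        with pytest.raises(DegenerateLabelsError):
            SparseHingeSVM().fit(X, y)

    def test_invalid_C_raises(self):
        with pytest.raises(ValueError):
            SparseHingeSVM(C=0.0).fit(np.zeros((4, 2)),
                                      np.array([1, 1, -1, -1]))

    def test_feature_count_mismatch_raises(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((8, 4))
        y = np.array([1, 1, 1, 1, -1, -1, -1, -1])
        m = SparseHingeSVM(C=1.0).fit(X, y)
        with pytest.raises(ValueError, match="features"):
            m.decision_function(rng.standard_normal((3, 3)))

    def test_sklearn_clone_and_params(self):
        m = SparseHingeSVM(C=2.5, standardize=False)
        c = clone(m)
        assert c.get_params()["C"] == 2.5
        assert c.get_params()["standardize"] is False
        c.set_params(C=7.0)
        assert c.C == 7.0

    def test_train_wrapper_attaches_feature_names(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((10, 3))
        y = np.array([1] * 5 + [-1] * 5)
        m = train(X, y, C=5.0, feature_names=("a", "b", "c"))
        assert m.feature_names_ == ("a", "b", "c")
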