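"""Dual SVM solver, weighted classifier and hyperparameter tuning."""

import numpy as np
import pytest
from scipy.optimize import minimize

from wsvm.svm import (DEFAULT_GRID, SMOSVC, SolverError, WeightedSVMClassifier,
                      rbf_kernel, rbf_kernel_matrix, tune)
from wsvm.synthetic import SyntheticSpec, generate_synthetic


def slsqp_dual_oracle(X, y, C, gamma):
    """Independent generic constrained-QP solve of the soft-margin dual."""
    K = rbf_kernel_matrix(X, X, gamma)
    Q = np.outer(y, y) * K
    res = minimize(
        lambda a: 0.5 * a @ Q @ a - a.sum(),
        np.zeros(len(y)),
        jac=lambda a: Q @ a - 1,
        bounds=[(0, C)] * len(y),
        constraints=[{"type": "eq", "fun": lambda a: a @ y, "jac": lambda a: y}],
        method="SLSQP",
        options={"maxiter": 1000, "ftol": 1e-12},
    )
    assert res.success
    return res.x, -res.fun


class TestRbfKernel:
    def test_zero_distance_is_one(self):
        assert rbf_kernel([1.0, 2.0], [1.0, 2.0], gamma=3.0) == 1.0

    def test_hand_evaluated_value(self):
        assert rbf_kernel([0, 0], [1, 1], gamma=0.5) == pytest.approx(
            np.exp(-1.0), abs=1e-12
        )

    def test_small_gamma_limit(self):
        assert rbf_kernel([0, 0], [100, 100], gamma=1e-12) == pytest.approx(1.0, abs=1e-6)

    def test_symmetric_and_bounded(self, rng):
        u, v = rng.normal(size=4), rng.normal(size=4)
        k = rbf_kernel(u, v, 1.3)
        assert k == rbf_kernel(v, u, 1.3)
        assert 0 < k <= 1

    def test_rejects_nonpositive_gamma(self):
        with pytest.raises(ValueError, match="gamma"):
            rbf_kernel([0.0], [1.0], gamma=0.0)


class TestSMOFit:
    def test_two_point_problem_is_symmetric(self):
        X = np.array([[0.0], [1.0]])
        y = np.array([-1, 1])
        m = SMOSVC(C=1e6, gamma=1.0).fit(X, y)
        dec = m.decision_function(X)
        np.testing.assert_array_equal(m.predict(X), y)
        assert abs(dec[0]) == pytest.approx(abs(dec[1]), abs=1e-8)
        # midpoint lies on the boundary; sign(0) -> +1 by convention
        mid = m.decision_function([[0.5]])[0]
        assert mid == pytest.approx(0.0, abs=1e-8)
        assert m.predict([[0.5]])[0] == 1

    def test_dual_equality_constraint(self, small_labeled_data):
        X, y = small_labeled_data
        m = SMOSVC(C=2.0, gamma=0.7).fit(X, y)
        assert abs(np.sum(m.dual_coef_)) < 1e-6

    def test_box_constraint_holds(self, small_labeled_data):
        X, y = small_labeled_data
        m = SMOSVC(C=2.0, gamma=0.7).fit(X, y)
        a = np.abs(m.dual_coef_)
        assert np.all(a >= -1e-12) and np.all(a <= 2.0 + 1e-12)

    def test_objective_matches_qp_oracle_on_small_instances(self):
        rng = np.random.default_rng(7)
        done = 0
        while done < 25:
            n = int(rng.integers(4, 9))
            X = rng.normal(size=(n, 2))
            y = np.where(rng.random(n) < 0.5, 1, -1)
            if len(np.unique(y)) < 2:
                continue
            C = float(rng.choice([0.5, 1.0, 10.0]))
            m = SMOSVC(C=C, gamma=1.0).fit(X, y)
            _, obj = slsqp_dual_oracle(X, y, C, 1.0)
            assert m.dual_objective_ == pytest.approx(obj, rel=1e-4, abs=1e-6)
            done += 1

    def test_separable_training_consistency(self):
        X = np.r_[np.full((10, 2), -2.0), np.full((10, 2), 2.0)]
        X += np.random.default_rng(0).normal(scale=0.1, size=X.shape)
        y = np.r_[-np.ones(10), np.ones(10)].astype(int)
        m = SMOSVC(C=100.0, gamma=0.5).fit(X, y)
        np.testing.assert_array_equal(m.predict(X), y)

    def test_single_class_errors(self):
        with pytest.raises(ValueError, match="two classes"):
            SMOSVC().fit(np.eye(3), np.ones(3, dtype=int))

    def test_nonconvergence_raises_with_diagnostics(self, small_labeled_data):
        X, y = small_labeled_data
        with pytest.raises(SolverError, match="did not converge"):
            SMOSVC(C=1.0, gamma=0.5, max_iter=2).fit(X, y)

    def test_training_error_nonincreasing_in_C(self, small_labeled_data):
        X, y = small_labeled_data
        errs = [
            np.mean(SMOSVC(C=C, gamma=0.5).fit(X, y).predict(X) != y)
            for C in [0.01, 0.1, 1.0, 10.0, 100.0]
        ]
        assert all(a >= b - 1e-12 for a, b in zip(errs, errs[1:]))


class TestPredict:
    def test_decision_values_match_kernel_sum_oracle(self, small_labeled_data, rng):
        X, y = small_labeled_data
        m = SMOSVC(C=1.5, gamma=0.8).fit(X, y)
        queries = rng.normal(size=(10, 3))
        dec = m.decision_function(queries)
        for q, d in zip(queries, dec):
            expl = sum(
                coef * rbf_kernel(sv, q, 0.8)
                for coef, sv in zip(m.dual_coef_, m.support_vectors_)
            )
            assert d == pytest.approx(expl + m.intercept_, abs=1e-10)

    def test_dimension_mismatch_errors(self, small_labeled_data):
        X, y = small_labeled_data
        m = SMOSVC().fit(X, y)
        with pytest.raises(ValueError):
            m.predict(np.zeros((2, 5)))


class TestWeightedClassifier:
    def test_uniform_weight_equivalence(self, rng):
        """w_j = 1/p at width gamma equals the unweighted SVM at gamma/p^2."""
        for _ in range(20):
            n, p = 40, int(rng.integers(2, 6))
            X = rng.normal(size=(n, p))
            y = np.where(X[:, 0] + rng.normal(size=n) > 0, 1, -1)
            gamma = float(rng.choice([0.5, 1.0, 2.0]))
            weighted = WeightedSVMClassifier(
                C=1.0, gamma=gamma, weights="uniform", standardize=False
            ).fit(X, y)
            plain = SMOSVC(C=1.0, gamma=gamma / p**2).fit(X, y)
            Xq = rng.normal(size=(30, p))
            np.testing.assert_array_equal(weighted.predict(Xq), plain.predict(Xq))
            # decision values agree to the solver's KKT tolerance scale
            np.testing.assert_allclose(
                weighted.decision_function(Xq), plain.decision_function(Xq),
                atol=1e-4,
            )

    def test_auto_weights_match_standalone_computation(self, small_labeled_data):
        from wsvm.weighting import point_biserial, weights_from_correlations
        X, y = small_labeled_data
        m = WeightedSVMClassifier(standardize=False).fit(X, y)
        r = [point_biserial(X[:, j], y) for j in range(3)]
        np.testing.assert_allclose(
            m.weight_vector_.weights, weights_from_correlations(r).weights
        )

    def test_standardization_uses_training_statistics(self, small_labeled_data):
        X, y = small_labeled_data
        m = WeightedSVMClassifier(standardize=True).fit(X, y)
        np.testing.assert_allclose(m.center_, X.mean(axis=0))
        np.testing.assert_allclose(m.scale_, X.std(axis=0, ddof=1))

    def test_continuous_mask_leaves_categorical_untouched(self, small_labeled_data):
        X, y = small_labeled_data
        X = X.copy()
        X[:, 2] = np.where(X[:, 2] > 0, 1.0, 0.0)
        m = WeightedSVMClassifier(
            standardize=True, continuous_mask=[True, True, False]
        ).fit(X, y)
        assert m.center_[2] == 0.0 and m.scale_[2] == 1.0

    def test_json_round_trip(self, small_labeled_data, rng):
        X, y = small_labeled_data
        m = WeightedSVMClassifier(C=2.0, gamma=0.3).fit(X, y)
        clone = WeightedSVMClassifier.from_json(m.to_json())
        Xq = rng.normal(size=(15, 3))
        np.testing.assert_allclose(
            m.decision_function(Xq), clone.decision_function(Xq), atol=1e-12
        )
        np.testing.assert_array_equal(m.predict(Xq), clone.predict(Xq))


def _separable_dataset(n=200, seed=2):
    return generate_synthetic(SyntheticSpec(
        n=n, class_prob=0.5,
        continuous_effects={"A": 3.0, "B": 3.0},
        seed=seed,
    ))


class TestTune:
    def test_single_candidate_is_selected(self, small_labeled_data):
        X, y = small_labeled_data
        res = tune(X, y, grid=[(1.0, 0.5)], k=5, seed=0)
        assert res.best == (1.0, 0.5)

    def test_deterministic_given_seed(self, small_labeled_data):
        X, y = small_labeled_data
        grid = [(0.5, 0.5), (4.0, 0.1)]
        a = tune(X, y, grid=grid, k=5, seed=3)
        b = tune(X, y, grid=grid, k=5, seed=3)
        assert a == b

    def test_near_separable_data_reaches_low_cv_error(self):
        ds = _separable_dataset()
        grid = [(1.0, g) for g in (0.05, 0.5)] + [(10.0, 0.5)]
        res = tune(ds.X, ds.y, grid=grid, k=10, seed=1)
        assert min(res.cv_error) == res.cv_error[res.grid.index(res.best)]
        assert res.cv_error[res.grid.index(res.best)] <= 0.05

    def test_tie_break_prefers_smaller_c_then_gamma(self):
        ds = _separable_dataset(n=100, seed=5)
        grid = [(8.0, 0.5), (1.0, 0.5), (1.0, 0.1)]
        res = tune(ds.X, ds.y, grid=grid, k=5, seed=0)
        errs = np.array(res.cv_error)
        tied = [g for g, e in zip(res.grid, errs) if e == errs.min()]
        assert res.best == min(tied)

    def test_k_larger_than_n_errors(self, small_labeled_data):
        X, y = small_labeled_data
        with pytest.raises(ValueError, match="exceeds"):
            tune(X, y, grid=[(1.0, 1.0)], k=100, seed=0)


def test_default_grid_is_the_documented_ladder():
    cs = sorted({c for c, _ in DEFAULT_GRID})
    gs = sorted({g for _, g in DEFAULT_GRID})
    assert cs == [2.0**e for e in range(-3, 10, 2)]
    assert gs == [2.0**e for e in range(-9, 2, 2)]
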