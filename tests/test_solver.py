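import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import sparseclogit as scl
from sparseclogit import likelihood, solver
from sparseclogit.data import DifferenceMatrix

from _oracles import convex_oracle, full_rank, lasso_quadratic_oracle, mle_exists
from conftest import random_instance


def _dm(rows, sizes, penalty_mask=None):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    sizes = np.asarray(sizes)
    return DifferenceMatrix(
        X=rows,
        row_stratum=np.repeat(np.arange(len(sizes)), sizes),
        stratum_sizes=sizes,
        penalty_mask=np.ones(rows.shape[1], dtype=bool) if penalty_mask is None else penalty_mask,
        variable_names=[f"x{j}" for j in range(rows.shape[1])],
    )


class TestSoftThreshold:
    @pytest.mark.parametrize("v,thr,expected", [(3.0, 1.0, 2.0), (-0.5, 1.0, 0.0),
                                                (-3.0, 1.0, -2.0), (0.7, 0.0, 0.7)])
    def test_values(self, v, thr, expected):
        assert solver.soft_threshold(v, thr) == expected

    @settings(deadline=None, max_examples=50)
    @given(st.floats(-1e6, 1e6), st.floats(0, 1e6))
    def test_shrinks_toward_zero_and_preserves_sign(self, v, thr):
        out = solver.soft_threshold(v, thr)
        assert abs(out) <= abs(v)
        assert out * v >= 0

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            solver.soft_threshold(1.0, -1.0)


class TestWeightedLassoCD:
    def test_identity_gram_closed_form(self):
        rng = np.random.default_rng(0)
        b = rng.normal(0, 2, 6)
        lam = 0.8
        gamma = solver.weighted_lasso_cd(np.eye(6), b, np.full(6, lam))
        expected = np.sign(b) * np.maximum(np.abs(b) - lam, 0)
        np.testing.assert_allclose(gamma, expected, atol=1e-12)

    def test_unpenalized_solves_linear_system(self):
        A = np.array([[2.0, 0.3], [0.3, 1.5]])
        b = np.array([1.0, -2.0])
        gamma = solver.weighted_lasso_cd(A, b, np.zeros(2), inner_tol=1e-14, max_sweeps=500)
        np.testing.assert_allclose(gamma, np.linalg.solve(A, b), atol=1e-10)

    def test_matches_generic_convex_solver(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            Q = rng.normal(size=(8, 5))
            A = Q.T @ Q + 0.1 * np.eye(5)
            b = rng.normal(0, 1, 5)
            lam_vec = np.full(5, 0.5)
            gamma = solver.weighted_lasso_cd(A, b, lam_vec, inner_tol=1e-13, max_sweeps=2000)
            g_o, f_o = lasso_quadratic_oracle(A, b, lam_vec)
            f_cd = 0.5 * gamma @ A @ gamma - b @ gamma + lam_vec @ np.abs(gamma)
            assert f_cd <= f_o + 1e-8

    def test_zero_curvature_penalized_coordinate_frozen(self):
        A = np.diag([1.0, 0.0])
        gamma = solver.weighted_lasso_cd(A, np.array([1.0, 5.0]), np.array([0.1, 0.1]))
        assert gamma[1] == 0.0

    def test_zero_curvature_unpenalized_coordinate_raises(self):
        A = np.diag([1.0, 0.0])
        with pytest.raises(np.linalg.LinAlgError, match="collinear"):
            solver.weighted_lasso_cd(A, np.array([1.0, 5.0]), np.array([0.1, 0.0]))


class TestLineSearch:
    def test_full_step_accepted_when_decreasing(self, small_matched):
        dm = scl.build_differences(small_matched.data)
        beta = np.zeros(dm.n_predictors)
        g = likelihood.gradient(dm, beta)
        step = solver.line_search(dm, beta, -0.01 * g, lam=0.0)
        assert step.t == 1.0
        assert step.armijo

    def test_backtracks_on_overlong_step(self, small_matched):
        dm = scl.build_differences(small_matched.data)
        beta = np.zeros(dm.n_predictors)
        g = likelihood.gradient(dm, beta)
        step = solver.line_search(dm, beta, -100.0 * g, lam=0.0, alpha1=0.25)
        assert 0 < step.t < 1
        # verify the Armijo inequality at the returned step
        f0 = likelihood.objective(dm, beta, 0.0)
        slope = float(g @ (-100.0 * g))
        assert step.objective <= f0 + 0.25 * step.t * slope + 1e-12

    def test_zero_direction_stalls(self, small_matched):
        dm = scl.build_differences(small_matched.data)
        beta = np.zeros(dm.n_predictors)
        step = solver.line_search(dm, beta, np.zeros(dm.n_predictors), lam=0.0)
        assert step.stalled


class TestFit:
    def test_beta_zero_at_lambda_max_one_iteration(self, small_matched):
        dm = scl.build_differences(small_matched.data)
        lam_max = scl.lambda_max(dm)
        res = scl.fit(dm, lam_max)
        assert res.converged
        assert res.n_outer == 1
        np.testing.assert_array_equal(res.beta, 0.0)
        assert res.n_nonzero == 0

    @pytest.mark.parametrize("M", [1, 3])
    def test_objective_matches_convex_oracle(self, M):
        rng = np.random.default_rng(100 + M)
        sim = scl.simulate_matched(scl.SimulationDesign(
            n_strata=30, n_controls=M, n_predictors=3,
            beta_true=np.array([0.5, -0.5, 0.0]), exposure_prevalence=0.3, seed=int(M)))
        dm = scl.build_differences(sim.data)
        lam = 0.2 * scl.lambda_max(dm)
        res = scl.fit(dm, lam)
        _, f_oracle = convex_oracle(dm, lam)
        assert res.objective <= f_oracle + 1e-6 * abs(f_oracle)

    def test_one_to_one_reduction_matches_sklearn_l1_logistic(self, small_matched):
        """1:1 conditional fit equals no-intercept L1 logistic on difference rows."""
        sklearn = pytest.importorskip("sklearn.linear_model")
        dm = scl.build_differences(small_matched.data)
        lam = 0.1 * scl.lambda_max(dm)
        res = scl.fit(dm, lam, config=solver.SolverConfig(kkt_tol=1e-7))
        # liblinear needs two classes: rows X labelled 1 plus mirrored rows -X
        # labelled 0 give exactly twice the one-class logistic loss, so the
        # penalty weight becomes C = 1/(2 lambda)
        X = np.asarray(dm.X)
        Xa = np.vstack([X, -X])
        ya = np.concatenate([np.ones(len(X)), np.zeros(len(X))])
        clf = sklearn.LogisticRegression(
            penalty="l1", C=1.0 / (2 * lam), fit_intercept=False, solver="liblinear",
            tol=1e-10, max_iter=10000)
        clf.fit(Xa, ya)
        np.testing.assert_allclose(res.beta, clf.coef_.ravel(), atol=1e-4)

    def test_objective_sequence_non_increasing(self):
        rng = np.random.default_rng(12)
        for _ in range(5):
            sim = random_instance(rng)
            dm = scl.build_differences(sim.data)
            lam = 0.3 * scl.lambda_max(dm)
            objs = []
            beta = np.zeros(dm.n_predictors)
            cfg = solver.SolverConfig()
            for _ in range(15):
                state = likelihood.stratum_state(dm, beta, weight_floor=cfg.weight_floor)
                A, b = solver.gram_system(dm, state)
                gamma = solver.weighted_lasso_cd(
                    A, b, np.where(dm.penalty_mask, lam, 0.0), beta_init=beta)
                if np.max(np.abs(gamma - beta)) == 0:
                    break
                step = solver.line_search(dm, beta, gamma - beta, lam,
                                          cfg.alpha1, cfg.alpha2)
                if step.stalled:
                    break
                objs.append(step.objective)
                beta = step.beta
            assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_sign_equivariance(self, small_1to3):
        dm = scl.build_differences(small_1to3.data)
        lam = 0.2 * scl.lambda_max(dm)
        res = scl.fit(dm, lam)
        X2 = dm.X.copy()
        X2[:, 1] = -X2[:, 1]
        dm2 = _dm(X2, dm.stratum_sizes)
        res2 = scl.fit(dm2, lam)
        np.testing.assert_allclose(res2.beta[1], -res.beta[1], atol=1e-10)
        others = [0, 2, 3]
        np.testing.assert_allclose(res2.beta[others], res.beta[others], atol=1e-10)

    def test_forced_covariate_stays_in_model(self, small_matched):
        data = small_matched.data
        data2 = scl.MatchedDataset(
            stratum_id=data.stratum_id, case_indicator=data.case_indicator,
            covariates=data.covariates,
            penalty_mask=[True, True, True, True, False],
            variable_names=data.variable_names)
        dm = scl.build_differences(data2)
        lam_max = scl.lambda_max(dm)
        res = scl.fit(dm, lam_max)
        assert np.all(res.beta[:4] == 0.0)
        assert res.beta[4] != 0.0  # forced covariate fitted freely

    def test_negative_lambda_rejected(self, small_matched):
        dm = scl.build_differences(small_matched.data)
        with pytest.raises(ValueError):
            scl.fit(dm, -1.0)

    def test_m1_gram_equals_finite_difference_hessian(self):
        """For 1:1 data, X^t W X is the exact Hessian of the likelihood."""
        rng = np.random.default_rng(13)
        X = rng.normal(size=(20, 3))
        dm = _dm(X, np.ones(20, dtype=int))
        beta = rng.normal(0, 0.5, 3)
        state = likelihood.stratum_state(dm, beta)
        A, _ = solver.gram_system(dm, state)
        h = 1e-5
        H_fd = np.zeros((3, 3))
        for j in range(3):
            e = np.zeros(3)
            e[j] = h
            H_fd[:, j] = (likelihood.gradient(dm, beta + e)
                          - likelihood.gradient(dm, beta - e)) / (2 * h)
        np.testing.assert_allclose(A, H_fd, atol=1e-6)


class TestKKTResidual:
    def test_zero_at_lambda_max_null_beta(self, small_matched):
        dm = scl.build_differences(small_matched.data)
        lam_max = scl.lambda_max(dm)
        assert solver.kkt_residual(dm, np.zeros(dm.n_predictors), lam_max) == pytest.approx(
            0.0, abs=1e-12)

    def test_half_lambda_max_at_null_beta(self, small_matched):
        dm = scl.build_differences(small_matched.data)
        lam_max = scl.lambda_max(dm)
        res = solver.kkt_residual(dm, np.zeros(dm.n_predictors), lam_max / 2)
        assert res == pytest.approx(lam_max / 2, abs=1e-12)

    def test_small_at_oracle_optimum(self):
        rng = np.random.default_rng(14)
        while True:
            sim = random_instance(rng, m_choices=(1, 2))
            dm = scl.build_differences(sim.data)
            if full_rank(dm) and mle_exists(dm):
                break
        lam = 0.3 * scl.lambda_max(dm)
        beta_o, _ = convex_oracle(dm, lam)
        # snap the oracle's near-zeros so the subgradient branch is exercised
        beta_o[np.abs(beta_o) < 1e-7] = 0.0
        assert solver.kkt_residual(dm, beta_o, lam) <= 1e-4

    def test_converged_fits_satisfy_kkt(self):
        rng = np.random.default_rng(15)
        for _ in range(10):
            sim = random_instance(rng)
            dm = scl.build_differences(sim.data)
            lam = float(rng.uniform(0.05, 0.9)) * scl.lambda_max(dm)
            res = scl.fit(dm, lam)
            if res.converged:
                assert res.kkt_residual <= 1e-4
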