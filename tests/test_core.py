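"""The selector optimization: objective, gradient, projection, solver,
exactness certificate, rounding, enumeration oracle, cross-validation."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from grip import (
    RegulationProblem, SolverConfig, brute_force_oracle, check_tightness,
    compute_M, cross_validate, gradient_G, infer_regulators, objective_G,
    project_capped_simplex, randomized_rounding, ridge_oracle,
    solve_relaxation,
)
from grip.core import sample_boolean_selectors
from tests.conftest import make_problem


def orthonormal_problem(rng, m=12, n=4, k=2, lam=0.0):
    Q, _ = np.linalg.qr(rng.standard_normal((m, n)))
    y = Q @ np.array([3.0, -2.0, 0.8, 0.1][:n])
    S = np.ones((n, n)) - np.eye(n)
    return RegulationProblem(y=y, X=Q, tf_ids=[f"T{i}" for i in range(n)],
                             S=S, rho=1.0, lam=lam, k=k)


class TestComputeM:
    def test_zero_selector_gives_identity(self, rng):
        X = rng.standard_normal((6, 4))
        np.testing.assert_allclose(compute_M(np.zeros(4), X, 1.0), np.eye(6))

    def test_woodbury_agrees_with_direct(self, rng):
        for _ in range(10):
            m, n = rng.integers(3, 12), rng.integers(2, 12)
            X = rng.standard_normal((m, n))
            u = rng.random(n)
            Md = compute_M(u, X, 1.0, "direct")
            Mw = compute_M(u, X, 1.0, "woodbury")
            assert np.abs(Md - Mw).max() < 1e-10

    def test_large_ridge_limit(self, rng):
        X = rng.standard_normal((5, 3))
        u = np.ones(3)
        rho = 1e8
        M = compute_M(u, X, rho)
        bound = np.linalg.norm(X @ X.T) / rho
        assert np.linalg.norm(M - np.eye(5)) <= bound * 1.01

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            compute_M(np.array([np.nan]), np.ones((2, 1)), 1.0)


class TestObjective:
    def test_zero_selector_is_y_norm(self, small_problem):
        val = objective_G(np.zeros(small_problem.n), small_problem)
        assert val == pytest.approx(float(small_problem.y @ small_problem.y))

    def test_hand_computed_two_by_two(self):
        # X = I2, y = (1,1), rho=1, u=1 -> y^T (2I)^-1 y = 1; u^T S u = 4
        p = RegulationProblem(y=np.ones(2), X=np.eye(2), tf_ids=["a", "b"],
                              S=np.array([[0.0, 2.0], [2.0, 0.0]]),
                              rho=1.0, lam=1.0, k=2)
        assert objective_G(np.ones(2), p) == pytest.approx(5.0)

    def test_equals_ridge_on_boolean_selectors(self, rng):
        for _ in range(30):
            p = make_problem(rng, m=int(rng.integers(5, 20)),
                             n=int(rng.integers(2, 8)), lam=0.0)
            u = (rng.random(p.n) < 0.5).astype(float)
            ref = ridge_oracle(np.flatnonzero(u), p.X, p.y, p.rho)
            assert objective_G(u, p) == pytest.approx(ref, abs=1e-8)


class TestRidgeOracle:
    def test_empty_support(self, rng):
        y = rng.standard_normal(7)
        assert ridge_oracle([], rng.standard_normal((7, 3)), y, 1.0) == \
            pytest.approx(float(y @ y))

    def test_orthonormal_closed_form(self, rng):
        p = orthonormal_problem(rng)
        c = p.X.T @ p.y
        for support in ([0], [1, 2], [0, 1, 2, 3]):
            expect = float(p.y @ p.y) - np.sum(c[support] ** 2) / 2.0
            assert ridge_oracle(support, p.X, p.y, 1.0) == \
                pytest.approx(expect, abs=1e-10)


class TestGradient:
    def test_at_zero_with_no_penalty(self, rng):
        p = make_problem(rng, lam=0.0)
        g = gradient_G(np.zeros(p.n), p)
        np.testing.assert_allclose(g, -(p.X.T @ p.y) ** 2 / p.rho, atol=1e-12)

    def test_zero_design_leaves_penalty_term(self, rng):
        p = RegulationProblem(y=np.zeros(4), X=np.zeros((4, 3)),
                              tf_ids=list("abc"),
                              S=np.array([[0, 1, 2], [1, 0, 1], [2, 1, 0.0]]),
                              rho=1.0, lam=0.7, k=2)
        u = np.array([0.2, 0.5, 0.1])
        np.testing.assert_allclose(gradient_G(u, p), 2 * 0.7 * (p.S @ u))

    def test_matches_central_finite_differences(self, rng):
        p = make_problem(rng, m=8, n=5, lam=0.3)
        h = 1e-6
        for _ in range(10):
            u = rng.uniform(0.1, 0.9, p.n)
            g = gradient_G(u, p)
            for i in range(p.n):
                e = np.zeros(p.n)
                e[i] = h
                fd = (objective_G(u + e, p) - objective_G(u - e, p)) / (2 * h)
                assert abs(g[i] - fd) <= 1e-5 * max(1.0, abs(fd))


class TestProjection:
    def test_already_feasible_unchanged(self):
        np.testing.assert_allclose(
            project_capped_simplex(np.array([0.2, 0.3]), 1.0), [0.2, 0.3])

    def test_symmetric_overflow(self):
        np.testing.assert_allclose(
            project_capped_simplex(np.array([2.0, 2.0]), 1.0), [0.5, 0.5])

    def test_boundary_case(self):
        np.testing.assert_allclose(
            project_capped_simplex(np.array([10.0, 0.2, -3.0]), 1.0),
            [1.0, 0.0, 0.0])

    def test_nonpositive_budget_rejected(self):
        with pytest.raises(ValueError):
            project_capped_simplex(np.array([1.0]), 0.0)

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(v=hnp.arrays(np.float64, st.integers(1, 40),
                        elements=st.floats(-5, 5)),
           k=st.floats(0.5, 8))
    def test_feasible_and_idempotent(self, v, k):
        u = project_capped_simplex(v, k)
        assert np.all(u >= 0) and np.all(u <= 1)
        assert u.sum() <= k + 1e-8
        np.testing.assert_allclose(project_capped_simplex(u, k), u, atol=1e-9)

    def test_matches_qp_oracle(self):
        from grip.experiments import projection_study
        res = projection_study(n_vectors=40, max_n=300, seed=3)
        assert res["max_abs_err"] < 1e-6


class TestSolver:
    def test_orthonormal_top_k_recovered(self, rng):
        p = orthonormal_problem(rng, k=2)
        sol = solve_relaxation(p, SolverConfig(seed=0))
        rounded = randomized_rounding(sol.u_hat, p, 50, 0)
        best = brute_force_oracle(p)
        # columns with the two largest |x_i^T y| are 0 and 1
        assert best.support == (0, 1)
        assert rounded.support == best.support

    def test_full_budget_selects_everything_beneficial(self, rng):
        p = orthonormal_problem(rng, n=3, k=3, lam=0.0)
        sol = solve_relaxation(p, SolverConfig(seed=0))
        best = brute_force_oracle(p)
        assert objective_G(sol.u_hat, p) <= best.objective + 1e-8

    def test_deterministic_across_runs(self, small_problem):
        cfg = SolverConfig(seed=123)
        a = solve_relaxation(small_problem, cfg)
        b = solve_relaxation(small_problem, cfg)
        np.testing.assert_array_equal(a.u_hat, b.u_hat)
        assert a.objective == b.objective and a.n_iterations == b.n_iterations

    def test_feasibility_of_solution(self, rng):
        for lam in (0.0, 0.5):
            p = make_problem(rng, lam=lam, k=2)
            sol = solve_relaxation(p)
            assert sol.u_hat.min() >= 0 and sol.u_hat.max() <= 1
            assert sol.u_hat.sum() <= p.k + 1e-8

    def test_objective_decreases_from_init(self, small_problem):
        u0 = np.full(small_problem.n, small_problem.k / small_problem.n)
        sol = solve_relaxation(small_problem)
        assert sol.objective <= objective_G(u0, small_problem) + 1e-12


class TestTightness:
    def test_boolean_optimum_is_certified(self, rng):
        p = orthonormal_problem(rng, k=2)
        best = brute_force_oracle(p)
        rep = check_tightness(best.u_tilde, p)
        assert rep.xi_exists
        assert rep.min_in > rep.max_out

    def test_tied_scores_across_budget_not_certified(self, rng):
        # two identical columns, budget 1: the relaxed optimum splits mass
        x = rng.standard_normal(10)
        z = rng.standard_normal(10) * 0.1
        X = np.column_stack([x, x, z])
        y = x.copy()
        S = np.ones((3, 3)) - np.eye(3)
        p = RegulationProblem(y=y, X=X, tf_ids=list("abc"), S=S,
                              rho=1.0, lam=0.0, k=1)
        sol = solve_relaxation(p, SolverConfig(seed=0))
        assert sol.u_hat[0] == pytest.approx(sol.u_hat[1], abs=1e-4)
        rep = check_tightness(sol, p)
        assert not rep.xi_exists

    def test_scores_follow_squared_correlations_orthonormal(self, rng):
        p = orthonormal_problem(rng, k=2)
        u = np.zeros(p.n)
        rep = check_tightness(u, p)
        np.testing.assert_allclose(rep.scores, (p.X.T @ p.y) ** 2, atol=1e-10)


class TestRounding:
    def test_boolean_input_returned(self, small_problem):
        u = np.array([1.0, 0.0, 1.0, 0.0, 0.0])
        out = randomized_rounding(u, small_problem, 10, 0, local_search=False)
        assert out.support == (0, 2)

    def test_pre_repair_draws_match_expectation(self):
        u = np.array([0.5, 0.5])
        draws = sample_boolean_selectors(u, 10_000, seed=1)
        se = np.sqrt(0.25 / 10_000)
        assert np.all(np.abs(draws.mean(axis=0) - 0.5) < 3 * se)

    def test_budget_respected_and_beneficial(self, rng):
        p = make_problem(rng, n=3, k=1, lam=0.0)
        u = np.array([0.9, 0.05, 0.05])
        out = randomized_rounding(u, p, 200, seed=2)
        assert len(out.support) <= 1
        assert out.objective <= objective_G(np.zeros(3), p) + 1e-12

    def test_local_search_escapes_zero_mass_support(self, rng):
        # the relaxed optimum can put zero mass on a coordinate of the best
        # Boolean support; the polish step must still reach the optimum
        for s in range(5):
            r = np.random.default_rng(s)
            p = make_problem(r, m=12, n=8, k=2, lam=0.0)
            sol = solve_relaxation(p, SolverConfig(seed=s))
            out = randomized_rounding(sol.u_hat, p, 100, seed=s)
            best = brute_force_oracle(p)
            assert out.objective <= best.objective * 1.01 + 1e-9

    def test_invalid_sample_count(self, small_problem):
        with pytest.raises(ValueError):
            randomized_rounding(np.zeros(5), small_problem, 0, 0)


class TestBruteForce:
    def test_single_candidate(self, rng):
        p = make_problem(rng, n=1, k=1)
        out = brute_force_oracle(p)
        assert out.support in ((), (0,))

    def test_huge_penalty_forces_single_tf(self, rng):
        p = make_problem(rng, n=5, k=3, lam=1e6)
        out = brute_force_oracle(p)
        assert len(out.support) <= 1

    def test_never_worse_than_pipeline(self, rng):
        for s in range(5):
            r = np.random.default_rng(100 + s)
            p = make_problem(r, n=8, k=2, lam=0.1)
            sol = solve_relaxation(p, SolverConfig(seed=s))
            out = randomized_rounding(sol.u_hat, p, 100, seed=s)
            best = brute_force_oracle(p)
            assert best.objective <= out.objective + 1e-12

    def test_budget_guard(self, rng):
        p = make_problem(rng, n=21, k=3)
        with pytest.raises(ValueError):
            brute_force_oracle(p)


class TestCrossValidate:
    def test_noiseless_planted_recovers_predictive_model(self,
                                                         noiseless_instance):
        p = noiseless_instance.problem
        choice, scores = cross_validate(
            p.X, p.y, p.S, rho_grid=(0.1, 1.0), lam_grid=(0.0, 0.5),
            k_grid=(3,), n_folds=3, seed=0)
        assert choice["k"] >= len(noiseless_instance.true_support) or \
            choice["cv_mse"] < 1e-2
        assert choice["cv_mse"] < 0.05

    def test_lam_zero_reduces_to_pure_sparse_model(self, rng):
        p = make_problem(rng, m=30, n=6, k=2)
        flat_S = np.ones((6, 6)) - np.eye(6)
        choice, _ = cross_validate(p.X, p.y, flat_S, rho_grid=(1.0,),
                                   lam_grid=(0.0, 0.1), k_grid=(2,),
                                   n_folds=3, seed=1)
        assert choice["lam"] in (0.0, 0.1)  # pipeline runs end-to-end

    def test_deterministic_selection(self, rng):
        p = make_problem(rng, m=40, n=6, k=2)
        a, _ = cross_validate(p.X, p.y, p.S, rho_grid=(0.5, 1.0),
                              lam_grid=(0.0, 0.2), k_grid=(1, 2),
                              n_folds=3, seed=9)
        b, _ = cross_validate(p.X, p.y, p.S, rho_grid=(0.5, 1.0),
                              lam_grid=(0.0, 0.2), k_grid=(1, 2),
                              n_folds=3, seed=9)
        assert a == b

    def test_lam_grid_must_contain_zero(self, rng):
        p = make_problem(rng, m=30, n=5)
        with pytest.raises(ValueError, match="lam grid"):
            cross_validate(p.X, p.y, p.S, lam_grid=(0.1,), n_folds=3)


class TestInferRegulators:
    def test_noiseless_planted_support_recovered(self, noiseless_instance):
        inst = noiseless_instance
        p = inst.problem
        res = infer_regulators(p.X, p.y, p.tf_ids, p.S,
                               config=SolverConfig(seed=0),
                               rho=1.0, lam=0.1, k=p.k)
        assert set(res.boolean.support) == set(inst.true_support)

    def test_full_budget_ranks_all(self, rng):
        p = make_problem(rng, n=4, k=4, lam=0.0)
        res = infer_regulators(p.X, p.y, p.tf_ids, p.S,
                               config=SolverConfig(seed=0),
                               rho=p.rho, lam=0.0, k=4)
        u = res.relaxed.u_hat
        got = [p.tf_ids.index(t) for t in res.ranked_tfs]
        assert sorted(got, key=lambda i: (-u[i], i)) == got

    def test_decoy_excluded_only_with_proximity_term(self, default_instance):
        inst = default_instance
        p = inst.problem
        d = inst.decoy_index
        res0 = infer_regulators(p.X, p.y, p.tf_ids, p.S,
                                config=SolverConfig(seed=0),
                                rho=1.0, lam=0.0, k=p.k)
        res1 = infer_regulators(p.X, p.y, p.tf_ids, p.S,
                                config=SolverConfig(seed=0),
                                rho=1.0, lam=1.0, k=p.k)
        assert d in res0.boolean.support
        assert d not in res1.boolean.support


class TestProximityMonotonicity:
    def test_mean_selected_distance_non_increasing_in_lam(self,
                                                          default_instance):
        p0 = default_instance.problem
        lams = [0.0, 0.1, 0.3, 0.6, 1.0]
        means = []
        for lam in lams:
            p = dataclasses.replace(p0, lam=lam)
            sol = solve_relaxation(p, SolverConfig(seed=0))
            out = randomized_rounding(sol.u_hat, p, 100, seed=0)
            idx = list(out.support)
            if len(idx) < 2:
                means.append(0.0)
                continue
            sub = p.S[np.ix_(idx, idx)]
            means.append(sub.sum() / (len(idx) * (len(idx) - 1)))
        # trend check: allow ties, no increase beyond tolerance
        assert all(b <= a + 1e-9 for a, b in zip(means, means[1:]))
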