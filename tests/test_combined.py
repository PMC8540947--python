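"""Joint TV-ONMF solvers: costs, updates, gradients, step sizes, drivers."""

import numpy as np
import pytest

from onmftv import CombinedConfig, CombinedONMFTV, run_combined, smoothed_tv
from onmftv.combined import (
    MinibatchPlan,
    cost_mul1,
    cost_mul2,
    cost_palm,
    grad_F,
    ipalm_step,
    mul1_step,
    mul2_step,
    palm_step,
    power_lambda_max,
    sgd_gradient_estimate,
    spring_epoch,
    step_size,
)
from onmftv.data import EPS_P1, FactorState
from onmftv.grid import SpatialGrid
from onmftv.tv import mm_weights, tv_descent_direction


def exact_state(rng, grid, K=2, N=8):
    """Binary-orthonormal U on the grid, X = UV exactly, W = U."""
    M = grid.n_pixels
    labels = rng.integers(0, K, size=M)
    labels[:K] = np.arange(K)
    U = np.zeros((M, K))
    U[np.arange(M), labels] = 1.0
    U /= np.sqrt(U.sum(axis=0))
    V = rng.uniform(0.5, 2.0, size=(K, N))
    X = U @ V
    return X, FactorState(U=U, V=V, W=U.copy())


def random_state_on(rng, grid, K=2, N=8):
    M = grid.n_pixels
    U = rng.uniform(0.1, 1.0, size=(M, K))
    V = rng.uniform(0.1, 1.0, size=(K, N))
    W = rng.uniform(0.1, 1.0, size=(M, K))
    X = rng.uniform(0.1, 2.0, size=(M, N))
    return X, FactorState(U=U, V=V, W=W)


class TestCosts:
    def test_mul1_cost_zero_at_exact_orthonormal_factorization(self, rng):
        grid = SpatialGrid.full(4, 4)
        X, st = exact_state(rng, grid)
        cfg = CombinedConfig(sigma1=2.0, sigma2=3.0, tau=0.0)
        assert cost_mul1(X, st.U, st.V, st.W, grid, cfg) == pytest.approx(0.0, abs=1e-20)

    def test_mul1_tv_term_of_constant_U(self, rng):
        grid = SpatialGrid.full(3, 3)
        U = np.full((9, 2), 0.4)
        V = rng.random((2, 5))
        X = U @ V
        tau, eps = 3.0, 1e-2
        with_tv = cost_mul1(X, U, V, U, grid,
                            CombinedConfig(sigma1=0, sigma2=0, tau=tau, eps_tv=eps))
        without = cost_mul1(X, U, V, U, grid,
                            CombinedConfig(sigma1=0, sigma2=0, tau=0.0, eps_tv=eps))
        assert with_tv - without == pytest.approx(tau / 2 * 9 * 2 * eps, rel=1e-12)

    def test_costs_match_term_by_term_loop(self, rng):
        grid = SpatialGrid.full(3, 3)
        X, st = random_state_on(rng, grid, K=2, N=5)
        cfg = CombinedConfig(sigma1=1.3, sigma2=0.7, tau=0.9, eps_tv=0.05)
        K = 2
        fit = sum(
            (X[m, n] - sum(st.U[m, k] * st.V[k, n] for k in range(K))) ** 2
            for m in range(9) for n in range(5)
        )
        orth = sum(
            ((1.0 if k == j else 0.0)
             - sum(st.W[m, k] * st.U[m, j] for m in range(9))) ** 2
            for k in range(K) for j in range(K)
        )
        tie = ((st.W - st.U) ** 2).sum()
        tv = smoothed_tv(st.U, grid, cfg.eps_tv)
        expected = 0.5 * fit + 0.5 * cfg.sigma1 * orth + 0.5 * cfg.sigma2 * tie \
            + 0.5 * cfg.tau * tv
        assert cost_mul1(X, st.U, st.V, st.W, grid, cfg) == pytest.approx(
            expected, rel=1e-12
        )
        orth_sym = sum(
            ((1.0 if k == j else 0.0)
             - sum(st.U[m, k] * st.U[m, j] for m in range(9))) ** 2
            for k in range(K) for j in range(K)
        )
        expected2 = 0.5 * fit + 0.25 * cfg.sigma1 * orth_sym + cfg.tau * tv
        assert cost_mul2(X, st.U, st.V, grid, cfg) == pytest.approx(
            expected2, rel=1e-12
        )


class TestMul1:
    def test_monotone_decrease(self, small_phantom):
        ph = small_phantom
        cfg = CombinedConfig(seed=2, max_iter=120)
        _, _, trace = run_combined(ph.data, "mul1", 3, cfg)
        diffs = np.diff(trace)
        assert diffs.max() <= 1e-10 * abs(trace[0])

    def test_exact_fixed_point_unchanged(self, rng):
        grid = SpatialGrid.full(5, 5)
        # K=1: constant membership column, exact factorization
        M = grid.n_pixels
        U = np.full((M, 1), 1.0 / np.sqrt(M))
        V = rng.uniform(0.5, 2.0, size=(1, 6))
        X = U @ V
        st = FactorState(U=U, V=V, W=U.copy())
        cfg = CombinedConfig(sigma1=1.0, sigma2=1.0, tau=2.0, eps_tv=1e-2)
        new = mul1_step(X, st, grid, cfg)
        assert np.abs(new.U - U).max() < 1e-12
        assert np.abs(new.V - V).max() < 1e-12
        assert np.abs(new.W - U).max() < 1e-12

    def test_single_sweep_matches_line_by_line_oracle(self, rng):
        grid = SpatialGrid.full(3, 3)
        X, st = random_state_on(rng, grid, K=2, N=4)
        cfg = CombinedConfig(sigma1=0.8, sigma2=1.2, tau=0.6, eps_tv=0.05)
        new = mul1_step(X, st, grid, cfg)
        # independent transcription of the three update lines
        U, V, W = st.U, st.V, st.W
        P, Z = mm_weights(U, grid, cfg.eps_tv)
        s12 = cfg.sigma1 + cfg.sigma2
        U_o = U * (X @ V.T + cfg.tau * P * Z + s12 * W) / (
            cfg.tau * P * U + cfg.sigma2 * U + U @ V @ V.T
            + cfg.sigma1 * W @ W.T @ U
        )
        U_o = np.clip(U_o, EPS_P1, 1e35)
        V_o = np.clip(V * (U_o.T @ X) / (U_o.T @ U_o @ V), EPS_P1, 1e35)
        W_o = np.clip(
            W * (s12 * U_o) / (cfg.sigma1 * U_o @ U_o.T @ W + cfg.sigma2 * W),
            EPS_P1, 1e35,
        )
        np.testing.assert_allclose(new.U, U_o, rtol=1e-12)
        np.testing.assert_allclose(new.V, V_o, rtol=1e-12)
        np.testing.assert_allclose(new.W, W_o, rtol=1e-12)

    def test_nonnegativity_after_every_sweep(self, rng):
        grid = SpatialGrid.full(4, 4)
        X, st = random_state_on(rng, grid, K=3, N=6)
        cfg = CombinedConfig(tau=1.0)
        for _ in range(10):
            st = mul1_step(X, st, grid, cfg)
            assert st.U.min() >= EPS_P1 and st.V.min() >= EPS_P1
            assert st.W.min() >= EPS_P1


class TestMul2:
    def test_constant_U_reduces_to_orthogonality_rule(self, rng):
        grid = SpatialGrid.full(4, 4)
        U = np.full((16, 2), 0.3)
        V = rng.uniform(0.5, 1.5, size=(2, 5))
        X = rng.uniform(0.1, 2.0, size=(16, 5))
        cfg = CombinedConfig(sigma1=1.1, tau=5.0, eps_tv=0.05)
        new = mul2_step(X, FactorState(U=U, V=V), grid, cfg)
        # TV direction of a constant matrix vanishes
        U_o = np.clip(
            U * (X @ V.T + cfg.sigma1 * U) / (U @ V @ V.T + cfg.sigma1 * U @ U.T @ U),
            EPS_P1, 1e35,
        )
        np.testing.assert_allclose(new.U, U_o, rtol=1e-12)

    def test_single_sweep_matches_oracle(self, rng):
        grid = SpatialGrid.full(3, 3)
        X, st = random_state_on(rng, grid, K=2, N=4)
        cfg = CombinedConfig(sigma1=0.9, tau=0.4, eps_tv=0.02)
        new = mul2_step(X, st, grid, cfg)
        U, V = st.U, st.V
        div = tv_descent_direction(U, grid, cfg.eps_tv)
        U_o = np.clip(
            U * (X @ V.T + cfg.tau * div + cfg.sigma1 * U)
            / (U @ V @ V.T + cfg.sigma1 * U @ U.T @ U),
            EPS_P1, 1e35,
        )
        V_o = np.clip(V * (U_o.T @ X) / (U_o.T @ U_o @ V), EPS_P1, 1e35)
        np.testing.assert_allclose(new.U, U_o, rtol=1e-12)
        np.testing.assert_allclose(new.V, V_o, rtol=1e-12)

    def test_v_update_shares_mul1_rule(self, rng):
        grid = SpatialGrid.full(3, 3)
        X, st = random_state_on(rng, grid, K=2, N=4)
        cfg = CombinedConfig(sigma1=0.0, sigma2=0.0, tau=0.0, eps_tv=0.01)
        n1 = mul1_step(X, FactorState(U=st.U, V=st.V, W=st.U.copy()), grid, cfg)
        n2 = mul2_step(X, FactorState(U=st.U, V=st.V), grid, cfg)
        # sigma = tau = 0: identical U updates, hence identical V updates
        np.testing.assert_allclose(n1.V, n2.V, rtol=1e-12)


class TestGradients:
    def test_zero_at_stationary_point(self, rng):
        grid = SpatialGrid.full(4, 4)
        X, st = exact_state(rng, grid)
        cfg = CombinedConfig(sigma1=1.5, sigma2=0.5, tau=0.0)
        gU, gV, gW = grad_F(X, st.U, st.V, st.W, cfg)
        assert np.abs(gU).max() < 1e-12
        assert np.abs(gV).max() < 1e-12
        assert np.abs(gW).max() < 1e-12

    def test_matches_central_finite_differences(self, rng):
        def F(X, U, V, W, cfg):
            K = U.shape[1]
            return (
                0.5 * np.linalg.norm(X - U @ V) ** 2
                + 0.5 * cfg.sigma1 * np.linalg.norm(np.eye(K) - W.T @ U) ** 2
                + 0.5 * cfg.sigma2 * np.linalg.norm(W - U) ** 2
            )

        cfg = CombinedConfig(sigma1=1.2, sigma2=0.8, tau=0.0)
        h = 1e-6
        for _ in range(5):
            U = rng.uniform(0.2, 1.0, size=(4, 3))
            V = rng.uniform(0.2, 1.0, size=(3, 5))
            W = rng.uniform(0.2, 1.0, size=(4, 3))
            X = rng.uniform(0.2, 1.5, size=(4, 5))
            gU, gV, gW = grad_F(X, U, V, W, cfg)
            for G, A, which in ((gU, U, "U"), (gV, V, "V"), (gW, W, "W")):
                fd = np.zeros_like(A)
                for idx in np.ndindex(A.shape):
                    Ap, Am = A.copy(), A.copy()
                    Ap[idx] += h
                    Am[idx] -= h
                    args_p = {"U": U, "V": V, "W": W}
                    args_m = {"U": U, "V": V, "W": W}
                    args_p[which] = Ap
                    args_m[which] = Am
                    fd[idx] = (F(X, **args_p, cfg=cfg) - F(X, **args_m, cfg=cfg)) / (2 * h)
                np.testing.assert_allclose(G, fd, rtol=1e-5, atol=1e-8)

    def test_sigma_zero_reduces_to_plain_nmf_gradient(self, rng):
        cfg = CombinedConfig(sigma1=0.0, sigma2=0.0, tau=0.0)
        U = rng.random((5, 2))
        V = rng.random((2, 6))
        W = rng.random((5, 2))
        X = rng.random((5, 6))
        gU, _, gW = grad_F(X, U, V, W, cfg)
        np.testing.assert_allclose(gU, (U @ V - X) @ V.T, rtol=1e-12)
        np.testing.assert_array_equal(gW, 0.0)


class TestStepSizes:
    def test_orthonormal_U_gives_unit_V_step(self, rng):
        U = np.linalg.qr(rng.normal(size=(10, 3)))[0]
        eta = step_size("V", U=U, cfg=CombinedConfig(tau=0.0),
                        rng=np.random.default_rng(0))
        assert eta == pytest.approx(1.0, rel=1e-8)

    def test_diagonal_V_known_top_eigenvalue(self):
        V = np.diag([3.0, 1.0])
        cfg = CombinedConfig(sigma1=0.0, sigma2=0.0, tau=0.0)
        eta = step_size("U", V=V, W=np.zeros((4, 2)), cfg=cfg,
                        rng=np.random.default_rng(1))
        assert eta == pytest.approx(1.0 / 9.0, rel=1e-8)

    def test_power_iteration_within_1pct_of_dense_eig(self, rng):
        cfg = CombinedConfig(tau=0.0, power_iters=50, sigma1=0.7, sigma2=0.3)
        for _ in range(10):
            V = rng.normal(size=(4, 10))
            W = rng.normal(size=(5, 4))
            U = rng.normal(size=(5, 4))
            exact_U = (
                np.linalg.eigvalsh(V @ V.T).max()
                + cfg.sigma1 * np.linalg.eigvalsh(W.T @ W).max()
                + cfg.sigma2
            )
            exact_V = np.linalg.eigvalsh(U.T @ U).max()
            est_U = 1.0 / step_size("U", V=V, W=W, cfg=cfg,
                                    rng=np.random.default_rng(3))
            est_V = 1.0 / step_size("V", U=U, cfg=cfg,
                                    rng=np.random.default_rng(3))
            assert est_U == pytest.approx(exact_U, rel=0.01)
            assert est_V == pytest.approx(exact_V, rel=0.01)

    def test_zero_matrix_returns_upper_clip(self):
        cfg = CombinedConfig(sigma1=0.0, sigma2=0.0, tau=0.0)
        eta = step_size("V", U=np.zeros((5, 2)), cfg=cfg,
                        rng=np.random.default_rng(0))
        assert eta == cfg.step_clip[1]


class TestPALMFamily:
    def test_degenerate_config_is_projected_gradient_descent(self, rng):
        grid = SpatialGrid.full(4, 4)
        X, st = random_state_on(rng, grid, K=2, N=6)
        cfg = CombinedConfig(sigma1=0.0, sigma2=0.0, tau=0.0)
        costs = [0.5 * np.linalg.norm(X - st.U @ st.V) ** 2]
        rng_p = np.random.default_rng(0)
        for _ in range(50):
            st = palm_step(X, st, grid, cfg, rng=rng_p)
            costs.append(0.5 * np.linalg.norm(X - st.U @ st.V) ** 2)
        assert costs[-1] < costs[0]

    def test_stationary_point_unchanged(self, rng):
        grid = SpatialGrid.full(5, 5)
        M = grid.n_pixels
        U = np.full((M, 1), 1.0 / np.sqrt(M))
        V = rng.uniform(0.5, 2.0, size=(1, 6))
        X = U @ V
        st = FactorState(U=U.copy(), V=V.copy(), W=U.copy())
        cfg = CombinedConfig(sigma1=1.0, sigma2=1.0, tau=0.5)
        new = palm_step(X, st, grid, cfg, rng=np.random.default_rng(0))
        assert np.abs(new.U - U).max() < 1e-10
        assert np.abs(new.V - V).max() < 1e-10
        assert np.abs(new.W - U).max() < 1e-10

    def test_spring_sr1_equals_palm_per_iterate(self, small_phantom):
        ph = small_phantom
        cfg_p = CombinedConfig(seed=9, max_iter=50, tau=50.0)
        cfg_s = CombinedConfig(seed=9, max_iter=50, tau=50.0, sr=1)
        st_p, _, tr_p = run_combined(ph.data, "palm", 3, cfg_p)
        st_s, _, tr_s = run_combined(ph.data, "spring", 3, cfg_s)
        np.testing.assert_allclose(tr_p, tr_s, atol=1e-8)
        np.testing.assert_allclose(st_p.U, st_s.U, atol=1e-8)
        np.testing.assert_allclose(st_p.V, st_s.V, atol=1e-8)

    def test_ipalm_beta_zero_is_palm(self, rng):
        grid = SpatialGrid.full(4, 4)
        X, st = random_state_on(rng, grid, K=2, N=6)
        st.W = st.U.copy()
        cfg = CombinedConfig(tau=1.0)
        a = palm_step(X, st, grid, cfg, rng=np.random.default_rng(5))
        b = ipalm_step(X, st, st, grid, cfg, rng=np.random.default_rng(5), beta=0.0)
        np.testing.assert_allclose(a.U, b.U, atol=1e-14)
        np.testing.assert_allclose(a.V, b.V, atol=1e-14)
        np.testing.assert_allclose(a.W, b.W, atol=1e-14)

    def test_ipalm_first_iteration_is_palm(self, rng):
        grid = SpatialGrid.full(4, 4)
        X, st = random_state_on(rng, grid, K=2, N=6)
        cfg = CombinedConfig(tau=1.0)
        a = palm_step(X, st, grid, cfg, rng=np.random.default_rng(5))
        b = ipalm_step(X, st, None, grid, cfg, rng=np.random.default_rng(5))
        np.testing.assert_allclose(a.U, b.U, atol=1e-14)

    def test_ipalm_not_slower_than_palm(self, small_phantom):
        """Momentum reaches a cost at iteration 200 no worse than plain
        PALM's (1% slack) — the practical speed-up the momentum buys."""
        ph = small_phantom
        cfg = CombinedConfig(seed=4, max_iter=200, tau=50.0)
        _, _, tr_p = run_combined(ph.data, "palm", 3, cfg)
        _, _, tr_i = run_combined(ph.data, "ipalm", 3, cfg)
        assert tr_i[-1] <= tr_p[-1] * 1.01

    def test_palm_objective_trend_decreases(self, small_phantom):
        ph = small_phantom
        cfg = CombinedConfig(seed=6, max_iter=60)
        _, _, trace = run_combined(ph.data, "palm", 3, cfg)
        # soft property: decrease over any 50-iteration window
        assert trace[50] < trace[0]
        assert trace[-1] <= min(trace[:10])


class TestSGDEstimator:
    def test_full_batch_equals_full_gradient(self, rng):
        cfg = CombinedConfig(sigma1=1.0, sigma2=0.5, tau=0.0)
        U, V, W = rng.random((6, 2)), rng.random((2, 9)), rng.random((6, 2))
        X = rng.random((6, 9))
        gU, gV, _ = grad_F(X, U, V, W, cfg)
        full = np.arange(9)
        np.testing.assert_allclose(
            sgd_gradient_estimate(X, U, V, W, full, cfg, "U"), gU, rtol=1e-12
        )
        np.testing.assert_allclose(
            sgd_gradient_estimate(X, U, V, W, full, cfg, "V"), gV, rtol=1e-12
        )

    def test_blocks_of_one_epoch_sum_to_full_gradient(self, rng):
        cfg = CombinedConfig(sigma1=0.7, sigma2=0.2, tau=0.0, sr=3)
        U, V, W = rng.random((5, 2)), rng.random((2, 12)), rng.random((5, 2))
        X = rng.random((5, 12))
        plan = MinibatchPlan.draw(12, 3, np.random.default_rng(0))
        gU, gV, _ = grad_F(X, U, V, W, cfg)
        sum_U = sum(sgd_gradient_estimate(X, U, V, W, b, cfg, "U")
                    for b in plan.blocks)
        sum_V = sum(sgd_gradient_estimate(X, U, V, W, b, cfg, "V")
                    for b in plan.blocks)
        np.testing.assert_allclose(sum_U, gU, rtol=1e-10)
        np.testing.assert_allclose(sum_V, gV, rtol=1e-10)

    def test_singleton_batches_match_hand_gradient(self, rng):
        cfg = CombinedConfig(sigma1=0.5, sigma2=0.25, tau=0.0)
        U, V, W = rng.random((4, 2)), rng.random((2, 3)), rng.random((4, 2))
        X = rng.random((4, 3))
        for n in range(3):
            est = sgd_gradient_estimate(X, U, V, W, [n], cfg, "U")
            r = U @ V[:, n] - X[:, n]
            hand = np.outer(r, V[:, n]) + (1 / 3) * (
                cfg.sigma1 * W @ (W.T @ U - np.eye(2)) + cfg.sigma2 * (U - W)
            )
            np.testing.assert_allclose(est, hand, rtol=1e-10)

    def test_empty_batch_rejected(self, rng):
        cfg = CombinedConfig(tau=0.0)
        with pytest.raises(ValueError):
            sgd_gradient_estimate(
                np.ones((2, 2)), np.ones((2, 1)), np.ones((1, 2)),
                np.ones((2, 1)), [], cfg, "U",
            )

    def test_expected_direction_is_unbiased(self, rng):
        """Monte-Carlo: sr * (single random block estimate) averages to the
        full gradient over many seeded plans."""
        cfg = CombinedConfig(sigma1=0.4, sigma2=0.3, tau=0.0, sr=4)
        U, V, W = rng.random((5, 2)), rng.random((2, 16)), rng.random((5, 2))
        X = rng.random((5, 16))
        gU, _, _ = grad_F(X, U, V, W, cfg)
        acc = np.zeros_like(gU)
        n_draws = 200
        plan_rng = np.random.default_rng(77)
        for _ in range(n_draws):
            plan = MinibatchPlan.draw(16, 4, plan_rng)
            j = plan_rng.integers(4)
            acc += 4 * sgd_gradient_estimate(X, U, V, W, plan.blocks[j], cfg, "U")
        rel = np.linalg.norm(acc / n_draws - gU) / np.linalg.norm(gU)
        assert rel <= 0.05


class TestMinibatchPlan:
    def test_blocks_disjoint_and_covering(self):
        plan = MinibatchPlan.draw(17, 5, np.random.default_rng(0))
        allidx = np.concatenate(plan.blocks)
        assert len(allidx) == 17
        assert len(np.unique(allidx)) == 17

    def test_spring_rejects_noncovering_plan(self, rng):
        grid = SpatialGrid.full(3, 3)
        X, st = random_state_on(rng, grid, K=2, N=6)
        st.W = st.U.copy()
        bad = MinibatchPlan(blocks=[np.array([0, 1])])
        with pytest.raises(ValueError, match="partition"):
            spring_epoch(X, st, grid, CombinedConfig(tau=0.0), bad)


class TestRunCombined:
    def test_unknown_method_rejected(self, small_phantom):
        with pytest.raises(ValueError, match="unknown method"):
            run_combined(small_phantom.data, "admm", 3, CombinedConfig())

    def test_same_seed_identical_traces(self, small_phantom):
        for method in ("mul1", "mul2", "palm", "ipalm", "spring"):
            cfg = CombinedConfig(seed=13, max_iter=10)
            _, la, ta = run_combined(small_phantom.data, method, 3, cfg)
            _, lb, tb = run_combined(small_phantom.data, method, 3, cfg)
            np.testing.assert_array_equal(ta, tb)
            np.testing.assert_array_equal(la.labels, lb.labels)

    def test_nonnegativity_of_final_factors(self, small_phantom):
        for method in ("mul1", "mul2", "palm", "ipalm", "spring"):
            st, _, _ = run_combined(
                small_phantom.data, method, 3, CombinedConfig(seed=1, max_iter=10)
            )
            assert st.U.min() >= 0 and st.V.min() >= 0
            if st.W is not None:
                assert st.W.min() >= 0

    def test_zero_noise_recovery(self, noisefree_phantom):
        from onmftv import evaluate_clustering

        ph = noisefree_phantom
        for method in ("palm", "ipalm"):
            _, cl, _ = run_combined(ph.data, method, 3,
                                    CombinedConfig(seed=2, max_iter=200))
            res = evaluate_clustering(cl.labels, ph.labels, n_clusters=3)
            assert res["vd_n"] == 0.0

    def test_orthogonality_residual_improves_on_clean_phantom(
        self, noisefree_phantom
    ):
        ph = noisefree_phantom
        from onmftv.initialization import init_svd

        def normalized_residual(A, B):
            # the model only identifies the product UV, so factor scale is
            # arbitrary; orthogonality is measured on unit columns
            An = A / np.linalg.norm(A, axis=0)
            Bn = B / np.linalg.norm(B, axis=0)
            return np.linalg.norm(np.eye(A.shape[1]) - Bn.T @ An)

        st0 = init_svd(ph.data.X, 3)
        r0 = normalized_residual(st0.U, st0.U)
        st, _, _ = run_combined(ph.data, "palm", 3,
                                CombinedConfig(seed=2, max_iter=200))
        assert normalized_residual(st.U, st.W) <= r0


class TestEstimator:
    def test_sklearn_api(self, small_phantom):
        from sklearn.base import clone

        est = CombinedONMFTV(n_clusters=3, solver="palm", random_state=0,
                             max_iter=20)
        cloned = clone(est)
        assert cloned.get_params() == est.get_params()
        labels = est.fit_predict(small_phantom.data)
        assert labels.shape == (small_phantom.data.n_spectra,)
        assert est.U_.shape[1] == 3
        assert est.n_iter_ == 20
        assert len(est.cost_trace_) == 21
        recon = est.reconstruction()
        assert recon.shape == small_phantom.data.X.shape

    def test_raw_matrix_with_coords(self, small_phantom):
        est = CombinedONMFTV(n_clusters=3, solver="mul1", random_state=0,
                             max_iter=10)
        est.fit(small_phantom.data.X, coords=small_phantom.data.grid.coords)
        assert est.W_ is not None

    def test_missing_grid_rejected(self, small_phantom):
        with pytest.raises(ValueError, match="grid"):
            CombinedONMFTV(n_clusters=3, max_iter=5).fit(small_phantom.data.X)

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            CombinedConfig(tau=-0.5)
        with pytest.raises(ValueError):
            CombinedConfig(sr=0)


def test_power_lambda_max_requires_positive_iters():
    with pytest.raises(ValueError):
        power_lambda_max(np.eye(2), n_iter=0)


def test_cost_palm_uses_unsmoothed_tv(rng):
    grid = SpatialGrid.full(3, 3)
    X, st = random_state_on(rng, grid, K=2, N=4)
    cfg = CombinedConfig(sigma1=0.0, sigma2=0.0, tau=2.0, eps_tv=0.5)
    base = 0.5 * np.linalg.norm(X - st.U @ st.V) ** 2
    expected = base + 2.0 * smoothed_tv(st.U, grid, 0.0)
    assert cost_palm(X, st.U, st.V, st.W, grid, cfg) == pytest.approx(
        expected, rel=1e-12
    )
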