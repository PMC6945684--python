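import numpy as np
import pytest
import scipy.sparse as sp

from ecgitv.graph import TrajectoryGraph, build_trajectory_graph, graph_tv_norm
from ecgitv.phantom import add_noise, forward_project, simulate_infarct, BSPSequence
from ecgitv.solvers import (
    DivergenceError,
    ReconResult,
    SolverParams,
    choose_steps,
    default_lambda,
    grad_fidelity,
    lipschitz_beta,
    prox_conjugate,
    soft_threshold,
    solve_graph_tv,
    solve_irtv,
    spectral_norm,
    tikhonov,
)


class TestSoftThreshold:
    @pytest.mark.parametrize(
        "x,theta,expected",
        [(3.0, 1.0, 2.0), (-0.5, 1.0, 0.0), (-3.0, 1.0, -2.0), (0.0, 2.0, 0.0)],
    )
    def test_scalar_values(self, x, theta, expected):
        assert soft_threshold(x, theta) == expected

    def test_zero_threshold_is_identity(self, rng):
        x = rng.normal(size=(4, 5))
        np.testing.assert_array_equal(soft_threshold(x, 0.0), x)

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            soft_threshold(1.0, -0.1)


class TestProxConjugate:
    def test_zero_is_fixed(self):
        assert prox_conjugate(np.zeros(3), 0.7, 1.0) == pytest.approx(0.0)

    def test_clips_to_mu_ball(self):
        # prox of the conjugate of mu*||.||_1 is a clip to [-mu, mu],
        # independent of the dual step
        for sigma in (0.1, 1.0, 10.0):
            assert prox_conjugate(5.0, sigma, 1.0) == pytest.approx(1.0)
            assert prox_conjugate(-5.0, sigma, 1.0) == pytest.approx(-1.0)
            assert prox_conjugate(0.3, sigma, 1.0) == pytest.approx(0.3)

    def test_moreau_identity(self, rng):
        # x = prox_{s g*}(x) + s * prox_{g/s}(x/s) for g = mu ||.||_1
        x = rng.normal(size=(6, 7)) * 3
        for sigma, mu in [(0.5, 1.0), (2.0, 0.3)]:
            lhs = prox_conjugate(x, sigma, mu) + sigma * soft_threshold(
                x / sigma, mu / sigma
            )
            np.testing.assert_allclose(lhs, x, atol=1e-12)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            prox_conjugate(1.0, 0.0, 1.0)


class TestLipschitzBeta:
    def test_identity(self):
        assert lipschitz_beta(np.eye(5)) == pytest.approx(2.0, rel=1e-10)

    def test_scaled_diagonal(self):
        assert lipschitz_beta(3.0 * np.eye(4)) == pytest.approx(18.0, rel=1e-10)

    def test_matches_svd_oracle(self, rng):
        H = rng.normal(size=(12, 20))
        expected = 2.0 * np.linalg.svd(H, compute_uv=False)[0] ** 2
        assert lipschitz_beta(H) == pytest.approx(expected, rel=1e-8)

    def test_sparse_operator(self, rng):
        D = sp.random(30, 20, density=0.2, random_state=1)
        expected = np.linalg.svd(D.toarray(), compute_uv=False)[0]
        assert spectral_norm(D) == pytest.approx(expected, rel=1e-8)

    def test_zero_matrix_rejected(self):
        with pytest.raises(ValueError):
            lipschitz_beta(np.zeros((3, 3)))


class TestChooseSteps:
    def test_hand_values(self):
        tau, sigma = choose_steps(2.0, 1.0, gamma=0.99)
        assert tau == pytest.approx(0.5)
        assert sigma == pytest.approx(0.99)

    def test_convergence_condition_holds(self, rng):
        for _ in range(20):
            beta = float(rng.uniform(0.1, 50))
            dn = float(rng.uniform(0.1, 20))
            tau, sigma = choose_steps(beta, dn)
            assert 1.0 / tau - sigma * dn**2 >= beta / 2.0 - 1e-12

    def test_gamma_to_one_gives_equality(self):
        tau, sigma = choose_steps(4.0, 2.0, gamma=1.0 - 1e-12)
        assert 1.0 / tau - sigma * 4.0 == pytest.approx(4.0 / 2.0, rel=1e-9)


class TestGradFidelity:
    def test_zero_at_exact_solution(self, rng):
        H = rng.normal(size=(6, 4))
        U = rng.normal(size=(4, 3))
        assert np.abs(grad_fidelity(H, U, H @ U)).max() == 0.0

    def test_identity_case(self, rng):
        U = rng.normal(size=(4, 3))
        np.testing.assert_allclose(grad_fidelity(np.eye(4), U, np.zeros((4, 3))), 2 * U)

    def test_finite_difference_oracle(self, rng):
        H = rng.normal(size=(5, 4))
        U = rng.normal(size=(4, 3))
        Phi = rng.normal(size=(5, 3))
        g = grad_fidelity(H, U, Phi)
        h = 1e-6
        for idx in [(0, 0), (2, 1), (3, 2)]:
            Up, Um = U.copy(), U.copy()
            Up[idx] += h
            Um[idx] -= h
            fd = (
                np.sum((H @ Up - Phi) ** 2) - np.sum((H @ Um - Phi) ** 2)
            ) / (2 * h)
            assert g[idx] == pytest.approx(fd, rel=1e-5, abs=1e-5)


class TestTikhonov:
    def test_identity_no_regularization(self, rng):
        Phi = rng.normal(size=(4, 6))
        np.testing.assert_allclose(tikhonov(np.eye(4), Phi, 0.0, np.eye(4)), Phi)

    def test_identity_unit_lambda_halves(self, rng):
        Phi = rng.normal(size=(4, 6))
        np.testing.assert_allclose(tikhonov(np.eye(4), Phi, 1.0, np.eye(4)), Phi / 2)

    def test_matches_dense_normal_equations(self, rng):
        H = rng.normal(size=(6, 4))
        Phi = rng.normal(size=(6, 3))
        L = rng.normal(size=(4, 4))
        lam = 0.37
        oracle = np.linalg.solve(H.T @ H + lam * L.T @ L, H.T @ Phi)
        np.testing.assert_allclose(tikhonov(H, Phi, lam, L), oracle, atol=1e-8)

    def test_sparse_laplacian_accepted(self, small_mesh, rng):
        n = small_mesh.n_nodes
        H = rng.normal(size=(16, n))
        Phi = rng.normal(size=(16, 2))
        U = tikhonov(H, Phi, 0.5, small_mesh.surface_laplacian)
        assert U.shape == (n, 2)

    def test_singular_system_raises(self):
        H = np.array([[1.0, 0.0, 0.0], [0.0, 1.0, 0.0]])
        with pytest.raises(np.linalg.LinAlgError):
            tikhonov(H, np.ones((2, 1)), 0.0, np.zeros((3, 3)))

    def test_default_lambda_scale(self, small_mesh, rng):
        H = rng.normal(size=(16, small_mesh.n_nodes))
        L = small_mesh.surface_laplacian
        lam = default_lambda(H, L)
        ratio = np.sum(H**2) / (L.multiply(L)).sum()
        assert lam == pytest.approx(0.01 * ratio, rel=1e-12)


def _toy_two_level_problem(rng, n=30, t=8, m=20):
    """Well-posed piecewise-constant toy: 2 clusters, graph from truth."""
    labels = np.zeros(n, dtype=bool)
    labels[: n // 3] = True
    U_true = np.where(labels[:, None], -84.0, 27.0) * np.ones((1, t))
    H = rng.normal(size=(m, n)) / np.sqrt(n)
    Phi = H @ U_true
    G = build_trajectory_graph(U_true, 3)
    return H, Phi, U_true, G, labels


class TestSolveGraphTV:
    def test_mu_zero_matches_least_squares(self, rng):
        H = rng.normal(size=(20, 15))
        Phi = rng.normal(size=(20, 6))
        G = build_trajectory_graph(rng.normal(size=(15, 6)), 3)
        res = solve_graph_tv(
            H, Phi, G,
            SolverParams(mu=0.0, max_iter=5000, tol=1e-12),
            U_init=np.zeros((15, 6)),
        )
        oracle = np.linalg.lstsq(H, Phi, rcond=None)[0]
        assert np.linalg.norm(res.U_hat - oracle) / np.linalg.norm(oracle) < 1e-5

    def test_truth_init_is_fixed_point(self, rng):
        H = rng.normal(size=(10, 6))
        U_true = rng.normal(size=(6, 4))
        G = build_trajectory_graph(U_true, 2)
        res = solve_graph_tv(
            H, H @ U_true, G, SolverParams(mu=0.0, max_iter=50), U_init=U_true
        )
        np.testing.assert_allclose(res.U_hat, U_true, atol=1e-12)
        assert res.converged

    def test_piecewise_constant_recovery(self, rng):
        H, Phi, U_true, G, _ = _toy_two_level_problem(rng)
        res = solve_graph_tv(
            H, Phi, G,
            SolverParams(mu=0.05, max_iter=3000, tol=1e-10),
            U_init=np.zeros_like(U_true),
        )
        assert np.abs(res.U_hat - U_true).max() < 1.0  # within 1 mV per node

    def test_objective_nonincreasing_overall(self, rng):
        H, Phi, U_true, G, _ = _toy_two_level_problem(rng)
        noisy = Phi + rng.normal(scale=0.1, size=Phi.shape)
        U0 = np.linalg.lstsq(H, noisy, rcond=None)[0]
        res = solve_graph_tv(
            H, noisy, G, SolverParams(mu=0.5, max_iter=200), U_init=U0
        )
        assert np.all(np.isfinite(res.objective_trace))
        assert res.objective_trace[-1] <= res.objective_trace[0] + 1e-9
        # the returned iterate is never worse than the starting point
        obj_returned = np.sum((H @ res.U_hat - noisy) ** 2) + 0.5 * graph_tv_norm(
            res.U_hat, G
        )
        assert obj_returned <= res.objective_trace[0] + 1e-9

    def test_scale_covariance(self, rng):
        H, Phi, U_true, G, _ = _toy_two_level_problem(rng, n=20, t=4, m=14)
        U0 = np.zeros_like(U_true)
        c = 2.5
        base = solve_graph_tv(H, Phi, G, SolverParams(mu=0.3, max_iter=80), U_init=U0)
        scaled = solve_graph_tv(
            H, c * Phi, G, SolverParams(mu=c * 0.3, max_iter=80), U_init=c * U0
        )
        np.testing.assert_allclose(scaled.U_hat, c * base.U_hat, rtol=1e-8, atol=1e-10)

    def test_divergent_input_raises(self, rng):
        H = rng.normal(size=(5, 4))
        Phi = np.full((5, 2), np.inf)
        G = build_trajectory_graph(rng.normal(size=(4, 2)), 2)
        with pytest.raises(DivergenceError):
            solve_graph_tv(H, Phi, G, SolverParams(mu=1.0), U_init=np.zeros((4, 2)))

    def test_unweighted_graph_rejected(self, rng):
        from ecgitv.graph import knn_graph

        skeleton = knn_graph(rng.normal(size=(6, 3)), 2)
        with pytest.raises(ValueError):
            solve_graph_tv(np.eye(6), np.zeros((6, 3)), skeleton,
                           SolverParams(), U_init=np.zeros((6, 3)))


class TestSolveIRTV:
    def test_single_outer_equals_plain_spatial_tv(self, rng):
        n, m, t = 15, 10, 3
        H = rng.normal(size=(m, n))
        Phi = rng.normal(size=(m, t))
        edges = [(i, i + 1) for i in range(n - 1)]
        U0 = np.zeros((n, t))
        params = SolverParams(mu=0.2, max_iter=400, tol=1e-12)
        res1 = solve_irtv(H, Phi, edges, params, U_init=U0, n_outer=1)
        # plain spatial TV via the graph-TV engine with unit weights
        g = TrajectoryGraph.from_edges(n, edges)
        res2 = solve_graph_tv(H, Phi, g, params, U_init=U0)
        np.testing.assert_allclose(res1.U_hat, res2.U_hat, atol=1e-10)

    def test_piecewise_constant_recovery(self, rng):
        # spatially contiguous two-level profile on a path graph
        n, m, t = 24, 16, 4
        labels = np.arange(n) < 8
        U_true = np.where(labels[:, None], -84.0, 27.0) * np.ones((1, t))
        H = rng.normal(size=(m, n)) / np.sqrt(n)
        Phi = H @ U_true
        edges = [(i, i + 1) for i in range(n - 1)]
        res = solve_irtv(
            H, Phi, edges,
            SolverParams(mu=0.05, max_iter=2000, tol=1e-10),
            U_init=np.zeros_like(U_true),
            inner_iter=2000,
        )
        assert np.abs(res.U_hat - U_true).max() < 1.0

    def test_returned_objective_not_worse_than_init(self, small_mesh, rng):
        mesh = small_mesh
        n = mesh.n_nodes
        H = rng.normal(size=(20, n)) / np.sqrt(n)
        truth = simulate_infarct(mesh, 1, 20.0, t=5)
        Phi = H @ truth.U + rng.normal(scale=0.5, size=(20, 5))
        U0 = np.zeros((n, 5))
        res = solve_irtv(H, Phi, mesh.spatial_edges,
                         SolverParams(mu=0.1, max_iter=100), U_init=U0)
        assert res.objective_trace[-1] <= res.objective_trace[0] + 1e-9
        assert np.all(np.isfinite(res.objective_trace))
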