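"""Inverse solvers: Tikhonov, graph-TV primal-dual, and reweighted spatial TV.

Three reconstructions of the TMP matrix U from body-surface potentials
Phi = H U + noise:

* :func:`tikhonov` — the classic second-order (surface-Laplacian) smoothness
  solution, solved in closed form.  It is both a baseline and the initial
  estimate from which the trajectory graph is built.
* :func:`solve_graph_tv` — minimises
  ``|| H U - Phi ||_F^2 + mu * || D U ||_1``
  where D is the weighted gradient operator of a trajectory-similarity
  graph, using a forward–backward primal-dual (Condat–Vu type) scheme: a
  gradient step on the smooth data term, a proximal (clipping) step on the
  dual of the L1 term.
* :func:`solve_irtv` — iteratively reweighted spatial TV, the classical
  frame-by-frame TV baseline: an outer loop updates per-edge weights
  ``w = 1/(|gradient| + eps)`` and the same primal-dual engine solves each
  weighted inner problem.

Step sizes: the data term h(U) = ||HU - Phi||_F^2 has gradient
2 H^T (H U - Phi) with Lipschitz constant beta = 2 ||H||_2^2.  We take the
primal step tau = 1/beta and the largest dual step sigma allowed by the
convergence condition  1/tau - sigma ||D||_2^2 >= beta/2,  scaled by a
safety factor gamma < 1.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import scipy.linalg
import scipy.sparse as sp

from .graph import TrajectoryGraph, _assemble_grad

__all__ = [
    "SolverParams",
    "ReconResult",
    "DivergenceError",
    "spectral_norm",
    "lipschitz_beta",
    "choose_steps",
    "soft_threshold",
    "prox_conjugate",
    "default_lambda",
    "tikhonov",
    "grad_fidelity",
    "solve_graph_tv",
    "solve_irtv",
]


class DivergenceError(RuntimeError):
    """Raised when an iterate becomes non-finite."""


@dataclass
class SolverParams:
    """Tunable solver parameters.

    mu : weight of the TV term against the data-fidelity term (>= 0)
    lambda_tik : Tikhonov regularisation weight; None picks the default
        scale 0.01 * tr(H^T H) / tr(L^T L)
    gamma : safety factor in (0, 1) applied to the largest admissible dual
        step
    max_iter, tol : stop when the relative Frobenius change of U drops
        below tol, or after max_iter iterations
    """

    mu: float = 1.0
    lambda_tik: Optional[float] = None
    gamma: float = 0.99
    max_iter: int = 500
    tol: float = 1e-5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.gamma < 1.0:
            raise ValueError(f"gamma must be in (0, 1), got {self.gamma}")
        if self.mu < 0:
            raise ValueError("mu must be >= 0")
        if self.lambda_tik is not None and self.lambda_tik < 0:
            raise ValueError("lambda_tik must be >= 0")


@dataclass
class ReconResult:
    """Reconstruction plus its solver trace.

    ``U_hat`` is the best-objective iterate encountered (the starting point
    included), and the last entry of ``objective_trace`` is its objective,
    so ``objective_trace[-1] <= objective_trace[0]`` always holds.
    """

    U_hat: np.ndarray
    objective_trace: np.ndarray
    tau: float
    sigma_dual: float
    beta: float
    n_iter: int
    converged: bool
    method: str = ""


# ---------------------------------------------------------------------------
# building blocks


def spectral_norm(A, tol: float = 1e-12, max_iter: int = 2000) -> float:
    """Largest singular value of a dense or sparse matrix by power iteration
    on A^T A, with a deterministic start vector."""
    n = A.shape[1]
    v = np.ones(n) + 1e-3 * np.linspace(0.0, 1.0, n)  # break symmetry
    v /= np.linalg.norm(v)
    s_prev = 0.0
    for _ in range(max_iter):
        w = A.T @ (A @ v)
        s = np.linalg.norm(w)
        if s == 0.0:
            return 0.0
        v = w / s
        if abs(s - s_prev) <= tol * max(s, 1.0):
            break
        s_prev = s
    return float(np.sqrt(s))


def lipschitz_beta(H: np.ndarray) -> float:
    """Lipschitz constant of the data-term gradient: beta = 2 ||H||_2^2."""
    s = spectral_norm(H)
    if s == 0.0:
        raise ValueError("H is the zero matrix; beta undefined")
    return 2.0 * s**2


def choose_steps(beta: float, D_norm: float, gamma: float = 0.99):
    """Primal/dual step sizes: tau = 1/beta and the largest dual step
    satisfying the convergence condition, scaled by gamma.

    Returns (tau, sigma_dual) with  1/tau - sigma_dual * D_norm^2 >= beta/2.
    """
    if beta <= 0 or D_norm <= 0:
        raise ValueError("beta and D_norm must be positive")
    tau = 1.0 / beta
    sigma_dual = gamma * beta / (2.0 * D_norm**2)
    assert 1.0 / tau - sigma_dual * D_norm**2 >= beta / 2.0 - 1e-12
    return tau, sigma_dual


def soft_threshold(x, theta):
    """Elementwise soft threshold sgn(x) * max(|x| - theta, 0) — the proximal
    operator of the L1 norm."""
    theta = np.asarray(theta, dtype=float)
    if np.any(theta < 0):
        raise ValueError("threshold must be >= 0")
    x = np.asarray(x, dtype=float)
    return np.sign(x) * np.maximum(np.abs(x) - theta, 0.0)


def prox_conjugate(x, sigma_dual: float, mu):
    """Proximal operator of the conjugate of g = mu * ||.||_1, evaluated via
    the Moreau decomposition  prox_{s g*}(x) = x - s prox_{g/s}(x/s).

    For the L1 norm this is an elementwise clip of x to [-mu, mu]; ``mu`` may
    be an array for entrywise-weighted penalties.
    """
    if sigma_dual <= 0:
        raise ValueError("sigma_dual must be positive")
    x = np.asarray(x, dtype=float)
    mu = np.asarray(mu, dtype=float)
    return x - sigma_dual * soft_threshold(x / sigma_dual, mu / sigma_dual)


def grad_fidelity(H: np.ndarray, U: np.ndarray, Phi: np.ndarray) -> np.ndarray:
    """Gradient of the data-fidelity term ||H U - Phi||_F^2, i.e.
    2 H^T (H U - Phi)."""
    if H.shape[1] != U.shape[0] or H.shape[0] != Phi.shape[0]:
        raise ValueError("dimension mismatch between H, U, Phi")
    return 2.0 * (H.T @ (H @ U - Phi))


# ---------------------------------------------------------------------------
# Tikhonov


def default_lambda(H: np.ndarray, L) -> float:
    """Default Tikhonov weight: 0.01 * tr(H^T H) / tr(L^T L), a scale that
    balances the two quadratic forms."""
    tr_h = float(np.sum(np.asarray(H) ** 2))
    if sp.issparse(L):
        tr_l = float((L.multiply(L)).sum())
    else:
        tr_l = float(np.sum(np.asarray(L) ** 2))
    return 0.01 * tr_h / tr_l


def tikhonov(
    H: np.ndarray,
    Phi: np.ndarray,
    lambda_tik: Optional[float] = None,
    L=None,
) -> np.ndarray:
    """Closed-form surface-Laplacian-regularised solution
    ``U = (H^T H + lambda L^T L)^{-1} H^T Phi`` via a Cholesky solve.

    Serves both as the initial estimate for the graph build and as the
    second-order Tikhonov baseline.
    """
    H = np.asarray(H, dtype=float)
    Phi = np.atleast_2d(np.asarray(Phi, dtype=float))
    if H.shape[0] != Phi.shape[0]:
        raise ValueError("H and Phi have inconsistent lead counts")
    n = H.shape[1]
    if L is None:
        L = sp.identity(n)
    if lambda_tik is None:
        lambda_tik = default_lambda(H, L)
    LtL = (L.T @ L).toarray() if sp.issparse(L) else np.asarray(L).T @ np.asarray(L)
    A = H.T @ H + lambda_tik * LtL
    try:
        c, low = scipy.linalg.cho_factor(A)
    except scipy.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "H^T H + lambda L^T L is rank-deficient; increase lambda_tik or "
            "check that L's null space is observed by H"
        ) from exc
    return scipy.linalg.cho_solve((c, low), H.T @ Phi)


# ---------------------------------------------------------------------------
# primal-dual engine


def _objective(H, U, Phi, D, mu) -> float:
    """mu may be scalar or an (E, t) array of entrywise weights."""
    resid = H @ U - Phi
    return float(np.sum(resid**2) + np.sum(mu * np.abs(D @ U)))


def _primal_dual(
    H: np.ndarray,
    Phi: np.ndarray,
    D: sp.spmatrix,
    mu,
    params: SolverParams,
    U_init: np.ndarray,
    method: str,
) -> ReconResult:
    """Forward–backward primal-dual iteration on
    min_U ||H U - Phi||_F^2 + sum(mu * |D U|).

    Primal step: gradient descent on the data term plus the dual coupling;
    dual step: ascent on D(2 U+ - U) followed by the conjugate-L1 prox
    (clipping to the entrywise radius mu).  Returns the best-objective
    iterate encountered, which makes the objective guarantee
    final <= initial unconditional even though the iteration itself is not
    monotone.
    """
    beta = lipschitz_beta(H)
    D_norm = spectral_norm(D)
    tau, sigma_dual = choose_steps(beta, D_norm, params.gamma)
    # convergence condition, asserted every run
    assert 1.0 / tau - sigma_dual * D_norm**2 >= beta / 2.0 - 1e-12, (
        "step sizes violate the primal-dual convergence condition"
    )

    U = np.array(U_init, dtype=float, copy=True)
    V = np.zeros((D.shape[0], U.shape[1]))
    trace = [_objective(H, U, Phi, D, mu)]
    best_obj, best_U = trace[0], U.copy()
    converged = False
    n_iter = 0
    scalar_mu = np.isscalar(mu) or np.asarray(mu).ndim == 0
    mu_is_zero = scalar_mu and float(np.asarray(mu)) == 0.0

    for n_iter in range(1, params.max_iter + 1):
        # non-finite values are detected explicitly below
        with np.errstate(invalid="ignore", over="ignore"):
            grad = 2.0 * (H.T @ (H @ U - Phi))
            U_new = U - tau * (grad + D.T @ V)
        if not np.all(np.isfinite(U_new)):
            raise DivergenceError(
                "non-finite iterate: primal step violated the condition "
                "1/tau - sigma ||D||^2 >= beta/2"
            )
        if not mu_is_zero:
            V = prox_conjugate(V + sigma_dual * (D @ (2.0 * U_new - U)), sigma_dual, mu)
        rel = np.linalg.norm(U_new - U) / max(np.linalg.norm(U), 1e-30)
        U = U_new
        obj = _objective(H, U, Phi, D, mu)
        trace.append(obj)
        if obj < best_obj:
            best_obj, best_U = obj, U.copy()
        if rel < params.tol:
            converged = True
            break

    trace.append(best_obj)  # objective of the returned iterate
    return ReconResult(
        U_hat=best_U,
        objective_trace=np.asarray(trace),
        tau=tau,
        sigma_dual=sigma_dual,
        beta=beta,
        n_iter=n_iter,
        converged=converged,
        method=method,
    )


def solve_graph_tv(
    H: np.ndarray,
    Phi: np.ndarray,
    G: TrajectoryGraph,
    params: Optional[SolverParams] = None,
    U_init: Optional[np.ndarray] = None,
    L=None,
) -> ReconResult:
    """Graph-TV reconstruction of the whole TMP sequence at once.

    If ``U_init`` is not given, the Tikhonov solution (with ``params.
    lambda_tik`` and the surface Laplacian ``L``) is used as the starting
    point — the same estimate the trajectory graph is normally built from.
    """
    params = params or SolverParams()
    if G.grad_operator is None:
        raise ValueError("graph has no weights; call compute_weights first")
    if U_init is None:
        if L is None:
            raise ValueError("either U_init or the surface Laplacian L is required")
        U_init = tikhonov(H, Phi, params.lambda_tik, L)
    return _primal_dual(H, Phi, G.grad_operator, params.mu, params, U_init, "graphtv")


def solve_irtv(
    H: np.ndarray,
    Phi: np.ndarray,
    spatial_edges: np.ndarray,
    params: Optional[SolverParams] = None,
    U_init: Optional[np.ndarray] = None,
    L=None,
    n_outer: int = 5,
    eps_scale: float = 1e-3,
    inner_iter: Optional[int] = None,
) -> ReconResult:
    """Iteratively reweighted spatial-TV baseline, frame by frame.

    Every frame is reconstructed independently under a spatial TV penalty
    whose edge weights are re-estimated from the current solution,
    ``w_e = 1 / (|(D0 u)_e| + eps)`` with ``eps = eps_scale * dynamic range``
    — the classic reweighted-L1 surrogate for L0 gradient sparsity.  Weights
    start uniform at 1, so a single outer iteration reduces to plain
    (unweighted) spatial TV.  All frames share H and the spatial incidence
    operator, so the inner problems are solved simultaneously with
    per-(edge, frame) clipping radii.

    The inner primal-dual loops are warm-started from the previous outer
    solution, so by default the total iteration budget ``params.max_iter``
    is split evenly across the ``n_outer`` reweighting stages
    (``inner_iter`` overrides the per-stage cap).
    """
    params = params or SolverParams()
    if n_outer < 1:
        raise ValueError("n_outer must be >= 1")
    if inner_iter is None:
        inner_iter = max(params.max_iter // n_outer, 20)
    inner_params = SolverParams(
        mu=params.mu, lambda_tik=params.lambda_tik, gamma=params.gamma,
        max_iter=inner_iter, tol=params.tol, seed=params.seed,
    )
    H = np.asarray(H, dtype=float)
    Phi = np.atleast_2d(np.asarray(Phi, dtype=float))
    n = H.shape[1]
    edges = np.asarray(spatial_edges, dtype=np.intp)
    D0 = _assemble_grad(edges, np.ones(edges.shape[0]), n)
    if U_init is None:
        if L is None:
            raise ValueError("either U_init or the surface Laplacian L is required")
        U_init = tikhonov(H, Phi, params.lambda_tik, L)

    w = np.ones((edges.shape[0], Phi.shape[1]))

    U = np.array(U_init, dtype=float, copy=True)
    best_obj = _objective(H, U, Phi, D0, params.mu)
    best_U = U.copy()
    trace = [best_obj]
    total_iter = 0
    converged = True
    last = None
    for outer in range(n_outer):
        last = _primal_dual(H, Phi, D0, params.mu * w, inner_params, U,
                            f"irtv[{outer}]")
        U = last.U_hat
        total_iter += last.n_iter
        converged = converged and last.converged
        obj = _objective(H, U, Phi, D0, params.mu)  # unweighted TV objective
        trace.append(obj)
        if obj < best_obj:
            best_obj, best_U = obj, U.copy()
        if outer < n_outer - 1:
            # eps tracks the current estimate's dynamic range so the
            # reweighting is scale-free
            eps = max(eps_scale * float(U.max() - U.min()), 1e-9)
            w = 1.0 / (np.abs(D0 @ U) + eps)

    trace.append(best_obj)  # objective of the returned iterate
    return ReconResult(
        U_hat=best_U,
        objective_trace=np.asarray(trace),
        tau=last.tau,
        sigma_dual=last.sigma_dual,
        beta=last.beta,
        n_iter=total_iter,
        converged=converged,
        method="irtv",
    )
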