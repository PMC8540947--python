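"""Joint TV-regularized orthogonal NMF solvers.

All five solvers minimize variants of

    1/2 ||X - UV||_F^2  +  orthogonality penalty on U  +  tau * TV(U),

differing in how the quartic orthogonality term is handled and in the
optimization scheme:

* ``mul1`` — majorize–minimization multiplicative updates on the split
  objective  1/2||X-UV||^2 + sigma1/2||I - W^T U||^2 + sigma2/2||W - U||^2
  + tau/2 TV_eps(U), with auxiliary variable ``W`` avoiding fourth-order
  terms.  Monotone cost decrease is guaranteed by construction.
* ``mul2`` — multiplicative update with the TV gradient (divergence
  direction) injected into the numerator; objective
  1/2||X-UV||^2 + sigma1/4||I - U^T U||^2 + tau TV_eps(U).  No descent
  guarantee.
* ``palm`` / ``ipalm`` / ``spring`` — proximal alternating linearized
  minimization on  F(U,V,W) + tau||U||_TV  (unsmoothed TV handled by its
  proximal operator, 5 inner dual-FISTA iterations), with power-iteration
  Lipschitz step sizes; ``ipalm`` adds per-block momentum extrapolation and
  ``spring`` replaces the U/V gradients by mini-batch SGD estimates over
  the channel index (the W update keeps the full gradient).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.utils.validation import check_array, check_is_fitted

from .data import (
    EPS_P1,
    EPS_P2,
    Clustering,
    FactorState,
    HyperspectralData,
    clip_positive,
)
from .grid import SpatialGrid
from .initialization import initialize
from .tv import mm_weights, smoothed_tv, tv_descent_direction, tv_prox
from .validation import hard_clustering

__all__ = [
    "CombinedConfig",
    "MinibatchPlan",
    "cost_mul1",
    "cost_mul2",
    "cost_palm",
    "mul1_step",
    "mul2_step",
    "grad_F",
    "power_lambda_max",
    "step_size",
    "palm_step",
    "ipalm_step",
    "sgd_gradient_estimate",
    "spring_epoch",
    "run_combined",
    "CombinedONMFTV",
]

_SOLVERS = ("mul1", "mul2", "palm", "ipalm", "spring")
_DEFAULT_MAX_ITER = {"mul1": 500, "mul2": 500, "palm": 300, "ipalm": 300, "spring": 100}

#: Per-solver TV weights selected by a grid search on the default phantom
#: (best stability and van Dongen criterion), used when ``tau`` is None.
#: The PALM family needs much larger nominal weights because the effective
#: prox weight is ``tau * eta`` with ``eta = 1/L`` of order 1e-4.
DEFAULT_TAU = {"mul1": 50.0, "mul2": 10.0, "palm": 500.0, "ipalm": 500.0, "spring": 50.0}


@dataclass
class CombinedConfig:
    """Hyperparameters shared by the combined solvers.

    ``step_clip`` bounds the PALM-family step sizes ``eta = 1/L_hat``;
    ``tau_eta_factor`` caps the effective TV weight ``tau * eta`` passed to
    the proximal operator at ``tau_eta_factor * tau``.
    """

    sigma1: float = 1.0
    sigma2: float = 1.0
    tau: float | None = None  # None: per-solver default (DEFAULT_TAU)
    eps_tv: float = 1e-2
    sr: int = 5
    max_iter: int | None = None
    seed: int | None = None
    step_clip: tuple[float, float] = (1e-8, 1e3)
    tau_eta_factor: float = 10.0
    prox_max_iter: int = 5
    power_iters: int = 20
    eps_p1: float = EPS_P1
    eps_p2: float = EPS_P2

    def __post_init__(self):
        if min(self.sigma1, self.sigma2, self.tau if self.tau is not None else 0) < 0:
            raise ValueError("sigma1, sigma2 and tau must be >= 0")
        if self.sr < 1 or int(self.sr) != self.sr:
            raise ValueError("sr must be a positive integer")

    def resolved(self, method: str) -> "CombinedConfig":
        """Copy with ``tau`` filled from the per-solver defaults if unset."""
        import dataclasses

        if self.tau is not None:
            return self
        return dataclasses.replace(self, tau=DEFAULT_TAU[method])


@dataclass
class MinibatchPlan:
    """Disjoint covering partition of the channel indices {0..N-1}."""

    blocks: list[np.ndarray] = field(default_factory=list)

    @classmethod
    def draw(cls, n_channels: int, sr: int, rng) -> "MinibatchPlan":
        perm = rng.permutation(n_channels)
        return cls(blocks=[np.sort(b) for b in np.array_split(perm, sr)])


def _check_finite(A: np.ndarray, name: str) -> None:
    if not np.all(np.isfinite(A)):
        raise FloatingPointError(
            f"non-finite entries appeared in matrix {name} during the update"
        )


# ---------------------------------------------------------------------------
# Objectives
# ---------------------------------------------------------------------------

def cost_mul1(X, U, V, W, grid: SpatialGrid, cfg: CombinedConfig) -> float:
    """Split MM objective with auxiliary variable W (tau/2-weighted TV)."""
    K = U.shape[1]
    fit = 0.5 * np.linalg.norm(X - U @ V) ** 2
    orth = 0.5 * cfg.sigma1 * np.linalg.norm(np.eye(K) - W.T @ U) ** 2
    tie = 0.5 * cfg.sigma2 * np.linalg.norm(W - U) ** 2
    return fit + orth + tie + 0.5 * cfg.tau * smoothed_tv(U, grid, cfg.eps_tv)


def cost_mul2(X, U, V, grid: SpatialGrid, cfg: CombinedConfig) -> float:
    """Quartic-penalty objective (sigma1/4-weighted) with tau-weighted TV."""
    K = U.shape[1]
    fit = 0.5 * np.linalg.norm(X - U @ V) ** 2
    orth = 0.25 * cfg.sigma1 * np.linalg.norm(np.eye(K) - U.T @ U) ** 2
    return fit + orth + cfg.tau * smoothed_tv(U, grid, cfg.eps_tv)


def cost_palm(X, U, V, W, grid: SpatialGrid, cfg: CombinedConfig) -> float:
    """PALM-family objective: smooth part F plus unsmoothed TV term J."""
    K = U.shape[1]
    fit = 0.5 * np.linalg.norm(X - U @ V) ** 2
    orth = 0.5 * cfg.sigma1 * np.linalg.norm(np.eye(K) - W.T @ U) ** 2
    tie = 0.5 * cfg.sigma2 * np.linalg.norm(W - U) ** 2
    return fit + orth + tie + cfg.tau * smoothed_tv(U, grid, 0.0)


# ---------------------------------------------------------------------------
# Multiplicative solvers
# ---------------------------------------------------------------------------

def mul1_step(
    X, state: FactorState, grid: SpatialGrid, cfg: CombinedConfig
) -> FactorState:
    """One MM sweep: multiplicative U, V, W updates with TV weight matrices.

    Preserves nonnegativity by construction and decreases
    :func:`cost_mul1` monotonically.
    """
    cfg = cfg.resolved("mul1")
    U, V, W = state.U, state.V, state.W
    s12 = cfg.sigma1 + cfg.sigma2
    P, Z = mm_weights(U, grid, cfg.eps_tv)
    num = X @ V.T + cfg.tau * P * Z + s12 * W
    den = cfg.tau * P * U + cfg.sigma2 * U + U @ (V @ V.T) + cfg.sigma1 * (
        W @ (W.T @ U)
    )
    U_new = clip_positive(U * num / den, cfg.eps_p1, cfg.eps_p2)
    _check_finite(U_new, "U")
    V_new = clip_positive(
        V * (U_new.T @ X) / (U_new.T @ U_new @ V), cfg.eps_p1, cfg.eps_p2
    )
    _check_finite(V_new, "V")
    if s12 > 0:
        W_new = clip_positive(
            W * (s12 * U_new)
            / (cfg.sigma1 * (U_new @ (U_new.T @ W)) + cfg.sigma2 * W),
            cfg.eps_p1,
            cfg.eps_p2,
        )
        _check_finite(W_new, "W")
    else:  # W decouples entirely when both penalties vanish
        W_new = W.copy()
    return FactorState(
        U=U_new, V=V_new, W=W_new, iteration=state.iteration + 1,
        cost_trace=state.cost_trace,
    )


def mul2_step(
    X, state: FactorState, grid: SpatialGrid, cfg: CombinedConfig
) -> FactorState:
    """One sweep of the divergence-direction multiplicative update.

    The TV gradient may make the numerator negative; the subsequent
    positivity projection restores nonnegativity.  No descent guarantee.
    """
    cfg = cfg.resolved("mul2")
    U, V = state.U, state.V
    div = tv_descent_direction(U, grid, cfg.eps_tv)
    num = X @ V.T + cfg.tau * div + cfg.sigma1 * U
    den = U @ (V @ V.T) + cfg.sigma1 * (U @ (U.T @ U))
    U_new = clip_positive(U * num / den, cfg.eps_p1, cfg.eps_p2)
    _check_finite(U_new, "U")
    V_new = clip_positive(
        V * (U_new.T @ X) / (U_new.T @ U_new @ V), cfg.eps_p1, cfg.eps_p2
    )
    _check_finite(V_new, "V")
    return FactorState(
        U=U_new, V=V_new, W=None, iteration=state.iteration + 1,
        cost_trace=state.cost_trace,
    )


# ---------------------------------------------------------------------------
# PALM family: gradients, step sizes, steps
# ---------------------------------------------------------------------------

def grad_F(X, U, V, W, cfg: CombinedConfig):
    """Partial gradients of the smooth part F of the PALM objective."""
    K = U.shape[1]
    I = np.eye(K)
    R = U @ V - X
    gU = R @ V.T + cfg.sigma1 * (W @ (W.T @ U - I)) + cfg.sigma2 * (U - W)
    gV = U.T @ R
    gW = cfg.sigma1 * (U @ (U.T @ W - I)) + cfg.sigma2 * (W - U)
    return gU, gV, gW


def power_lambda_max(A: np.ndarray, n_iter: int = 20, rng=None) -> float:
    """Largest eigenvalue of a symmetric PSD matrix via power iteration."""
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    k = A.shape[0]
    b = rng.standard_normal(k)
    nb = np.linalg.norm(b)
    if nb == 0 or not np.any(A):
        return 0.0
    b /= nb
    lam = 0.0
    for _ in range(n_iter):
        Ab = A @ b
        norm = np.linalg.norm(Ab)
        if norm == 0:
            return 0.0
        b = Ab / norm
        lam = float(b @ (A @ b))
    return lam


def step_size(
    block: str,
    U=None,
    V=None,
    W=None,
    cfg: CombinedConfig | None = None,
    rng=None,
) -> float:
    """Power-iteration step size ``eta = 1 / L_hat`` for one PALM block.

    Lipschitz moduli of the partial gradients:
    U-block ``lam_max(V V^T) + sigma1 lam_max(W W^T) + sigma2``;
    V-block ``lam_max(U^T U)``;
    W-block ``sigma1 lam_max(U^T U) + sigma2``.
    The estimate is clipped to ``cfg.step_clip``.
    """
    cfg = cfg or CombinedConfig()
    it = cfg.power_iters
    if block == "U":
        L = (
            power_lambda_max(V @ V.T, it, rng)
            + cfg.sigma1 * power_lambda_max(W.T @ W, it, rng)
            + cfg.sigma2
        )
    elif block == "V":
        L = power_lambda_max(U.T @ U, it, rng)
    elif block == "W":
        L = cfg.sigma1 * power_lambda_max(U.T @ U, it, rng) + cfg.sigma2
    else:
        raise ValueError(f"unknown block {block!r}")
    lo, hi = cfg.step_clip
    if L <= 0:
        return hi
    return float(np.clip(1.0 / L, lo, hi))


def _prox_tv_nonneg(U, grid, tau_eta, cfg):
    if tau_eta > 0:
        U = tv_prox(U, grid, tau_eta, max_iter=cfg.prox_max_iter)
    return np.maximum(U, 0.0)


def palm_step(
    X, state: FactorState, grid: SpatialGrid, cfg: CombinedConfig, rng=None
) -> FactorState:
    """One PALM iteration: prox-gradient U, projected-gradient V and W."""
    cfg = cfg.resolved("palm")
    U, V, W = state.U, state.V, state.W
    eta_U = step_size("U", V=V, W=W, cfg=cfg, rng=rng)
    gU, _, _ = grad_F(X, U, V, W, cfg)
    tau_eta = min(cfg.tau * eta_U, cfg.tau_eta_factor * cfg.tau)
    U = _prox_tv_nonneg(U - eta_U * gU, grid, tau_eta, cfg)
    _check_finite(U, "U")
    eta_V = step_size("V", U=U, cfg=cfg, rng=rng)
    _, gV, _ = grad_F(X, U, V, W, cfg)
    V = np.maximum(V - eta_V * gV, 0.0)
    _check_finite(V, "V")
    eta_W = step_size("W", U=U, cfg=cfg, rng=rng)
    _, _, gW = grad_F(X, U, V, W, cfg)
    W = np.maximum(W - eta_W * gW, 0.0)
    _check_finite(W, "W")
    return FactorState(
        U=U, V=V, W=W, iteration=state.iteration + 1, cost_trace=state.cost_trace
    )


def ipalm_step(
    X,
    state: FactorState,
    prev_state: FactorState | None,
    grid: SpatialGrid,
    cfg: CombinedConfig,
    rng=None,
    beta: float | None = None,
) -> FactorState:
    """PALM step taken from per-block extrapolated points (momentum).

    ``beta`` defaults to the Nesterov-like ramp ``(i - 1) / (i + 2)`` capped
    at 0.45 — the nonconvex inertial-PALM admissibility bound (beta < 1/2
    for unscaled ``1/L`` steps); with ``beta = 0`` (or on the first
    iteration) this is exactly :func:`palm_step`.
    """
    cfg = cfg.resolved("ipalm")
    i = state.iteration + 1
    if beta is None:
        beta = min(max(0.0, (i - 1.0) / (i + 2.0)), 0.45)
    if prev_state is None:
        beta = 0.0
        prev_state = state
    U, V, W = state.U, state.V, state.W
    Ue = U + beta * (U - prev_state.U)
    eta_U = step_size("U", V=V, W=W, cfg=cfg, rng=rng)
    gU, _, _ = grad_F(X, Ue, V, W, cfg)
    tau_eta = min(cfg.tau * eta_U, cfg.tau_eta_factor * cfg.tau)
    U_new = _prox_tv_nonneg(Ue - eta_U * gU, grid, tau_eta, cfg)
    _check_finite(U_new, "U")
    Ve = V + beta * (V - prev_state.V)
    eta_V = step_size("V", U=U_new, cfg=cfg, rng=rng)
    _, gV, _ = grad_F(X, U_new, Ve, W, cfg)
    V_new = np.maximum(Ve - eta_V * gV, 0.0)
    _check_finite(V_new, "V")
    We = W + beta * (W - prev_state.W)
    eta_W = step_size("W", U=U_new, cfg=cfg, rng=rng)
    _, _, gW = grad_F(X, U_new, V_new, We, cfg)
    W_new = np.maximum(We - eta_W * gW, 0.0)
    _check_finite(W_new, "W")
    return FactorState(
        U=U_new, V=V_new, W=W_new, iteration=i, cost_trace=state.cost_trace
    )


def sgd_gradient_estimate(
    X, U, V, W, batch, cfg: CombinedConfig, block: str
) -> np.ndarray:
    """SGD gradient estimate over a channel mini-batch.

    F is split column-wise over the channels,
    ``F = sum_n [ 1/2 ||X_:n - U V_:n||^2 + (1/N) F_tilde(U, W) ]``,
    and the estimate sums the per-channel gradients over the batch.  With
    the full batch this equals the exact partial gradient; summed over the
    disjoint blocks of one epoch it equals the full gradient exactly.
    """
    batch = np.asarray(batch, dtype=np.int64)
    if batch.size == 0:
        raise ValueError("empty mini-batch")
    N = X.shape[1]
    K = U.shape[1]
    Rb = U @ V[:, batch] - X[:, batch]
    if block == "U":
        frac = batch.size / N
        orth = cfg.sigma1 * (W @ (W.T @ U - np.eye(K))) + cfg.sigma2 * (U - W)
        return Rb @ V[:, batch].T + frac * orth
    if block == "V":
        out = np.zeros_like(V)
        out[:, batch] = U.T @ Rb
        return out
    raise ValueError("block must be 'U' or 'V'")


def spring_epoch(
    X,
    state: FactorState,
    grid: SpatialGrid,
    cfg: CombinedConfig,
    plan: MinibatchPlan,
    rng=None,
) -> FactorState:
    """One SPRING epoch: ``sr`` stochastic inner steps over the plan blocks.

    U and V use SGD gradient estimates restricted to the current block; the
    W update always uses the full gradient.  With ``sr = 1`` the epoch is
    per-iterate identical to :func:`palm_step`.
    """
    cfg = cfg.resolved("spring")
    covered = np.sort(np.concatenate(plan.blocks))
    if covered.size != X.shape[1] or np.any(covered != np.arange(X.shape[1])):
        raise ValueError("mini-batch plan must partition the channel indices")
    U, V, W = state.U, state.V, state.W
    for batch in plan.blocks:
        eta_U = step_size("U", V=V, W=W, cfg=cfg, rng=rng)
        gU = sgd_gradient_estimate(X, U, V, W, batch, cfg, "U")
        tau_eta = min(cfg.tau * eta_U, cfg.tau_eta_factor * cfg.tau)
        U = _prox_tv_nonneg(U - eta_U * gU, grid, tau_eta, cfg)
        _check_finite(U, "U")
        eta_V = step_size("V", U=U, cfg=cfg, rng=rng)
        gV = sgd_gradient_estimate(X, U, V, W, batch, cfg, "V")
        V = np.maximum(V - eta_V * gV, 0.0)
        _check_finite(V, "V")
        eta_W = step_size("W", U=U, cfg=cfg, rng=rng)
        _, _, gW = grad_F(X, U, V, W, cfg)
        W = np.maximum(W - eta_W * gW, 0.0)
        _check_finite(W, "W")
    return FactorState(
        U=U, V=V, W=W, iteration=state.iteration + 1, cost_trace=state.cost_trace
    )


# ---------------------------------------------------------------------------
# Drivers
# ---------------------------------------------------------------------------

def _objective(method, X, state, grid, cfg):
    if method == "mul1":
        return cost_mul1(X, state.U, state.V, state.W, grid, cfg)
    if method == "mul2":
        return cost_mul2(X, state.U, state.V, grid, cfg)
    return cost_palm(X, state.U, state.V, state.W, grid, cfg)


def run_combined(
    data: HyperspectralData,
    method: str,
    n_clusters: int,
    cfg: CombinedConfig,
    init: str | None = None,
) -> tuple[FactorState, Clustering, list[float]]:
    """Run one combined solver to its iteration cap and hard-cluster.

    Returns the final factor state, the hard clustering of ``U``, and the
    per-iteration objective trace (initial cost first).
    """
    if method not in _SOLVERS:
        raise ValueError(f"unknown method {method!r}; choose from {_SOLVERS}")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    X, grid = data.X, data.grid
    cfg = cfg.resolved(method)
    max_iter = cfg.max_iter or _DEFAULT_MAX_ITER[method]
    ss = np.random.SeedSequence(cfg.seed)
    seed_init, seed_power, seed_plan, seed_tie = ss.spawn(4)
    rng_power = np.random.default_rng(seed_power)
    rng_plan = np.random.default_rng(seed_plan)

    init_method = init or "svd"
    state = initialize(
        data, n_clusters, method=init_method, seed=seed_init,
        eps_p1=cfg.eps_p1, eps_p2=cfg.eps_p2,
    )
    needs_W = method in ("mul1", "palm", "ipalm", "spring")
    if needs_W:
        state.W = state.U.copy()

    state.cost_trace = [_objective(method, X, state, grid, cfg)]
    prev = None
    for _ in range(max_iter):
        if method == "mul1":
            new = mul1_step(X, state, grid, cfg)
        elif method == "mul2":
            new = mul2_step(X, state, grid, cfg)
        elif method == "palm":
            new = palm_step(X, state, grid, cfg, rng=rng_power)
        elif method == "ipalm":
            new = ipalm_step(X, state, prev, grid, cfg, rng=rng_power)
            prev = state
        else:  # spring
            plan = MinibatchPlan.draw(X.shape[1], cfg.sr, rng_plan)
            new = spring_epoch(X, state, grid, cfg, plan, rng=rng_power)
        new.cost_trace.append(_objective(method, X, new, grid, cfg))
        state = new
    labels = hard_clustering(state.U, seed=seed_tie)
    return state, labels, state.cost_trace


class CombinedONMFTV(ClusterMixin, BaseEstimator):
    """Spatially coherent clustering by joint TV-regularized orthogonal NMF.

    Scikit-learn-style clusterer.  ``fit`` requires the pixel grid of the
    spectra (pass ``grid=`` or ``coords=``); the fitted membership matrix
    ``U_`` yields hard labels by row maximum.

    Parameters
    ----------
    n_clusters : int
        Number of clusters K.
    solver : {"mul1", "mul2", "palm", "ipalm", "spring"}
        Optimization scheme (see the module docstring).
    sigma1, sigma2 : float
        Orthogonality penalty weights (``sigma2`` is ignored by ``mul2``).
    tau : float, optional
        Total-variation weight; 0 disables the spatial coupling.  ``None``
        selects the per-solver grid-searched default (``DEFAULT_TAU``).
    eps_tv : float
        TV smoothing constant for the multiplicative solvers.
    sr : int
        Number of mini-batches per SPRING epoch (1/sr = batch fraction).
    max_iter : int, optional
        Iteration cap; defaults to 500 (mul1/mul2), 300 (palm/ipalm) or
        100 epochs (spring).
    init : {"svd", "kmeans++"}, optional
        Factor initialization; defaults to the deterministic SVD-based one.
    random_state : int, optional
        Master seed for all stochastic choices of one run.

    Attributes
    ----------
    U_ : ndarray of shape (M, K)
        Fitted cluster membership matrix.
    V_ : ndarray of shape (K, N)
        Fitted centroid (characteristic spectra) matrix.
    W_ : ndarray of shape (M, K) or None
        Auxiliary orthogonality variable, where the solver uses one.
    labels_ : ndarray of shape (M,)
        Hard cluster assignment of every spectrum.
    cost_trace_ : list of float
        Objective value per iteration (initial value first).
    """

    def __init__(
        self,
        n_clusters: int = 6,
        solver: str = "palm",
        sigma1: float = 1.0,
        sigma2: float = 1.0,
        tau: float | None = None,
        eps_tv: float = 1e-2,
        sr: int = 5,
        max_iter: int | None = None,
        init: str | None = None,
        random_state: int | None = None,
        step_clip: tuple[float, float] = (1e-8, 1e3),
        tau_eta_factor: float = 10.0,
        power_iters: int = 20,
        eps_p1: float = EPS_P1,
        eps_p2: float = EPS_P2,
    ):
        self.n_clusters = n_clusters
        self.solver = solver
        self.sigma1 = sigma1
        self.sigma2 = sigma2
        self.tau = tau
        self.eps_tv = eps_tv
        self.sr = sr
        self.max_iter = max_iter
        self.init = init
        self.random_state = random_state
        self.step_clip = step_clip
        self.tau_eta_factor = tau_eta_factor
        self.power_iters = power_iters
        self.eps_p1 = eps_p1
        self.eps_p2 = eps_p2

    def _config(self) -> CombinedConfig:
        return CombinedConfig(
            sigma1=self.sigma1,
            sigma2=self.sigma2,
            tau=self.tau,
            eps_tv=self.eps_tv,
            sr=self.sr,
            max_iter=self.max_iter,
            seed=self.random_state,
            step_clip=self.step_clip,
            tau_eta_factor=self.tau_eta_factor,
            power_iters=self.power_iters,
            eps_p1=self.eps_p1,
            eps_p2=self.eps_p2,
        )

    def fit(self, X, y=None, *, grid: SpatialGrid | None = None, coords=None):
        """Fit on spectra ``X`` (M × N) located on ``grid`` (or ``coords``)."""
        if isinstance(X, HyperspectralData):
            data = X
        else:
            X = check_array(X, dtype=float)
            if grid is None:
                if coords is None:
                    raise ValueError(
                        "pass grid= or coords= so the TV term knows the "
                        "pixel layout"
                    )
                grid = SpatialGrid(coords)
            data = HyperspectralData(
                X=clip_positive(X, self.eps_p1, self.eps_p2), grid=grid
            )
        state, clustering, trace = run_combined(
            data, self.solver, self.n_clusters, self._config(), init=self.init
        )
        self.U_ = state.U
        self.V_ = state.V
        self.W_ = state.W
        self.labels_ = clustering.labels
        self.cost_trace_ = trace
        self.n_iter_ = state.iteration
        return self

    def fit_predict(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).labels_

    def reconstruction(self) -> np.ndarray:
        """Low-rank reconstruction ``U_ @ V_`` of the fitted data."""
        check_is_fitted(self, "U_")
        return self.U_ @ self.V_
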