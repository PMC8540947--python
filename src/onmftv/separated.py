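"""Separated workflow: classical ONMF clustering, then TV denoising of U.

The two-stage baseline: an orthogonal-NMF engine produces a membership
matrix ``U`` and centroids ``V`` from the spectra alone; the spatial
coherence is then imposed afterwards by applying the TV proximal operator
column-wise to ``U`` (dual FISTA, 100 iterations) and projecting negative
entries to zero.  Both the pre-TV and post-TV hard clusterings are kept so
the benefit of the spatial step can be quantified.

Engines
-------
kmeans  Lloyd's K-means from k-means++ seeds (binary memberships).
choi    Alternating multiplicative orthogonal updates,
        ``U <- U ∘ (X V^T) / (U V X^T U)``.
ding    Square-root-form multiplicative orthogonal update,
        ``U <- U ∘ sqrt((X V^T) / (U U^T X V^T))``.
kimura  HALS, column-wise on U / row-wise on V, orthogonality enforced by
        subtracting cross-column projections.
li      HALS with an additive approximate-orthogonality penalty and
        nonnegativity projections.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import KMeans

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
from .tv import tv_prox
from .validation import hard_clustering

__all__ = [
    "ENGINES",
    "DEFAULT_TAU",
    "engine_kmeans",
    "engine_choi_step",
    "engine_ding_step",
    "engine_kimura_step",
    "engine_li_step",
    "run_engine",
    "run_separated",
    "SeparatedONMFTV",
]

ENGINES = ("kmeans", "choi", "ding", "kimura", "li")

#: Per-engine TV post-processing weights selected by a grid search on the
#: default phantom (best van Dongen criterion after the TV step).  K-means
#: memberships are binary (unit-height jumps), hence the larger weight.
DEFAULT_TAU = {"kmeans": 0.2, "choi": 0.05, "ding": 0.05, "kimura": 0.02, "li": 0.05}

#: Engines for which k-means++ initialization outperforms the SVD one.
_KMEANSPP_ENGINES = ("kmeans", "ding")


def engine_kmeans(X, n_clusters: int, seed=None, max_iter: int = 300) -> FactorState:
    """Lloyd's K-means (k-means++ seeding, single start) as an ONMF engine.

    Returns binary memberships ``U`` and the centroids ``V``; the K-means
    objective equals ``||X - U V||_F^2`` for this pair.
    """
    seed_int = int(np.random.default_rng(seed).integers(2**31 - 1))
    km = KMeans(
        n_clusters=n_clusters,
        init="k-means++",
        n_init=1,
        max_iter=max_iter,
        random_state=seed_int,
        algorithm="lloyd",
    ).fit(X)
    M = X.shape[0]
    U = np.zeros((M, n_clusters))
    U[np.arange(M), km.labels_] = 1.0
    return FactorState(U=U, V=km.cluster_centers_.copy())


def engine_choi_step(X, U, V, eps_p1=EPS_P1, eps_p2=EPS_P2):
    """One sweep of the alternating multiplicative orthogonal updates."""
    U = clip_positive(U * (X @ V.T) / (U @ (V @ (X.T @ U))), eps_p1, eps_p2)
    V = clip_positive(V * (U.T @ X) / (U.T @ U @ V), eps_p1, eps_p2)
    return U, V


def engine_ding_step(X, U, V, eps_p1=EPS_P1, eps_p2=EPS_P2):
    """One sweep of the square-root-form multiplicative orthogonal updates."""
    XVt = X @ V.T
    U = clip_positive(U * np.sqrt(XVt / (U @ (U.T @ XVt))), eps_p1, eps_p2)
    V = clip_positive(V * (U.T @ X) / (U.T @ U @ V), eps_p1, eps_p2)
    return U, V


def _reseed_column(X, U, V, k, rng=None):
    """Re-initialize a collapsed U column from the residual's positive part."""
    R = X - U @ V
    col = np.maximum(R @ V[k], 0.0)
    if not np.any(col):
        col = np.maximum(X @ V[k], 0.0)
    norm = np.linalg.norm(col)
    return col / norm if norm > 0 else np.full(U.shape[0], 1.0 / np.sqrt(U.shape[0]))


def engine_kimura_step(X, U, V, eps_p1=EPS_P1, eps_p2=EPS_P2):
    """One HALS sweep, column-wise on U and row-wise on V.

    Orthogonality of the U columns is promoted by subtracting, after the
    least-squares column update, the projections onto the remaining columns
    (Lagrange-multiplier handling of the constraint); negative intermediates
    are projected to zero before the positivity clipping.
    """
    U = U.copy()
    V = V.copy()
    K = U.shape[1]
    A = X @ V.T           # (M, K)
    B = V @ V.T           # (K, K)
    for k in range(K):
        denom = max(B[k, k], eps_p1)
        u = (A[:, k] - U @ B[:, k] + U[:, k] * B[k, k]) / denom
        for ell in range(K):
            if ell == k:
                continue
            nrm2 = float(U[:, ell] @ U[:, ell])
            if nrm2 > 1e-12:
                u = u - U[:, ell] * (float(U[:, ell] @ u) / nrm2)
        u = np.maximum(u, 0.0)
        if not np.any(u > eps_p1 * 10):
            u = _reseed_column(X, U, V, k)
        U[:, k] = np.clip(u, eps_p1, eps_p2)
    C = U.T @ X           # (K, N)
    G = U.T @ U           # (K, K)
    for k in range(K):
        denom = max(G[k, k], eps_p1)
        v = (C[k] - G[k] @ V + G[k, k] * V[k]) / denom
        V[k] = np.clip(np.maximum(v, 0.0), eps_p1, eps_p2)
    return U, V


def engine_li_step(X, U, V, orth_weight: float = 0.5, eps_p1=EPS_P1, eps_p2=EPS_P2):
    """One HALS sweep with an additive approximate-orthogonality penalty.

    Each U column minimizes its least-squares subproblem plus
    ``orth_weight * u^T (sum of the other columns)``, followed by the
    nonnegativity projection.
    """
    U = U.copy()
    V = V.copy()
    K = U.shape[1]
    A = X @ V.T
    B = V @ V.T
    for k in range(K):
        denom = max(B[k, k], eps_p1)
        others = U.sum(axis=1) - U[:, k]
        u = (A[:, k] - U @ B[:, k] + U[:, k] * B[k, k] - orth_weight * others) / denom
        u = np.maximum(u, 0.0)
        if not np.any(u > eps_p1 * 10):
            u = _reseed_column(X, U, V, k)
        U[:, k] = np.clip(u, eps_p1, eps_p2)
    C = U.T @ X
    G = U.T @ U
    for k in range(K):
        denom = max(G[k, k], eps_p1)
        v = (C[k] - G[k] @ V + G[k, k] * V[k]) / denom
        V[k] = np.clip(np.maximum(v, 0.0), eps_p1, eps_p2)
    return U, V


_STEP_FUNCS = {
    "choi": engine_choi_step,
    "ding": engine_ding_step,
    "kimura": engine_kimura_step,
    "li": engine_li_step,
}


def run_engine(
    X,
    engine: str,
    n_clusters: int,
    seed=None,
    max_iter: int = 500,
    init: str | None = None,
) -> FactorState:
    """Run one classical ONMF engine to its sweep cap."""
    if engine not in ENGINES:
        raise ValueError(f"unknown engine {engine!r}; choose from {ENGINES}")
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if engine == "kmeans":
        return engine_kmeans(X, n_clusters, seed=seed, max_iter=max_iter)
    init_method = init or (
        "kmeans++" if engine in _KMEANSPP_ENGINES else "svd"
    )
    state = initialize(X, n_clusters, method=init_method, seed=seed)
    U, V = state.U, state.V
    step = _STEP_FUNCS[engine]
    for _ in range(max_iter):
        U, V = step(X, U, V)
    return FactorState(U=U, V=V, iteration=max_iter)


def run_separated(
    data: HyperspectralData,
    engine: str,
    n_clusters: int,
    tau: float | None = None,
    seed=None,
    max_iter: int = 500,
    init: str | None = None,
    prox_max_iter: int = 100,
) -> tuple[FactorState, Clustering, Clustering]:
    """Classical ONMF followed by column-wise TV denoising of U.

    Returns ``(state, clustering_before_tv, clustering_after_tv)``; the
    state's ``U`` is the denoised, nonnegativity-projected matrix.
    """
    if tau is None:
        tau = DEFAULT_TAU[engine] if engine in DEFAULT_TAU else 0.1
    ss = np.random.SeedSequence(seed)
    seed_engine, seed_tie = ss.spawn(2)
    state = run_engine(
        data.X, engine, n_clusters, seed=seed_engine, max_iter=max_iter, init=init
    )
    before = hard_clustering(state.U, seed=seed_tie)
    if tau > 0:
        U_tv = tv_prox(state.U, data.grid, tau, max_iter=prox_max_iter)
        U_tv = np.maximum(U_tv, 0.0)  # project negative entries to zero
    else:
        U_tv = state.U.copy()
    after = hard_clustering(U_tv, seed=seed_tie)
    state = FactorState(U=U_tv, V=state.V, iteration=state.iteration)
    return state, before, after


class SeparatedONMFTV(ClusterMixin, BaseEstimator):
    """Two-stage spatially coherent clustering: ONMF engine, then TV denoise.

    Parameters
    ----------
    n_clusters : int
        Number of clusters K.
    engine : {"kmeans", "choi", "ding", "kimura", "li"}
        Classical ONMF engine for the first stage.
    tau : float, optional
        TV weight of the post-processing proximal step; 0 skips it and
        ``None`` selects the per-engine grid-searched default
        (``DEFAULT_TAU``).
    max_iter : int
        Engine sweep cap (Lloyd iteration cap for ``kmeans``).
    init : {"svd", "kmeans++"}, optional
        Override of the per-engine initialization default.
    random_state : int, optional
        Master seed (engine seeding and tie-breaks).

    Attributes
    ----------
    U_, V_ : fitted factors (``U_`` is the TV-denoised membership matrix).
    labels_ : hard clustering after the TV step.
    labels_pre_tv_ : hard clustering before the TV step.
    """

    def __init__(
        self,
        n_clusters: int = 6,
        engine: str = "kmeans",
        tau: float | None = None,
        max_iter: int = 500,
        init: str | None = None,
        random_state: int | None = None,
        prox_max_iter: int = 100,
    ):
        self.n_clusters = n_clusters
        self.engine = engine
        self.tau = tau
        self.max_iter = max_iter
        self.init = init
        self.random_state = random_state
        self.prox_max_iter = prox_max_iter

    def fit(self, X, y=None, *, grid: SpatialGrid | None = None, coords=None):
        if isinstance(X, HyperspectralData):
            data = X
        else:
            X = np.asarray(X, dtype=float)
            if grid is None:
                if coords is None:
                    raise ValueError("pass grid= or coords= for the TV step")
                grid = SpatialGrid(coords)
            data = HyperspectralData(X=clip_positive(X), grid=grid)
        state, before, after = run_separated(
            data,
            self.engine,
            self.n_clusters,
            self.tau,
            seed=self.random_state,
            max_iter=self.max_iter,
            init=self.init,
            prox_max_iter=self.prox_max_iter,
        )
        self.U_ = state.U
        self.V_ = state.V
        self.labels_ = after.labels
        self.labels_pre_tv_ = before.labels
        return self

    def fit_predict(self, X, y=None, **fit_params):
        return self.fit(X, y, **fit_params).labels_
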