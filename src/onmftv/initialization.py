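"""Factor-matrix initialization: K-means++ seeding or NNDSVD-style SVD.

Both initializers return strictly positive matrices (after the element-wise
``[eps_p1, eps_p2]`` projection), which multiplicative solvers require to
avoid zero locking.  Columns of ``U`` are normalized to unit Euclidean norm
(with the scale absorbed into ``V``) so that ``U^T U`` starts close to the
identity targeted by the orthogonality penalties.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import kmeans_plusplus

from .data import EPS_P1, EPS_P2, FactorState, HyperspectralData, clip_positive

__all__ = ["init_kmeanspp", "init_svd", "initialize"]


def _normalize_columns(U: np.ndarray, V: np.ndarray):
    norms = np.linalg.norm(U, axis=0)
    norms = np.where(norms > 0, norms, 1.0)
    return U / norms, V * norms[:, None]


def init_kmeanspp(
    data: HyperspectralData | np.ndarray,
    n_clusters: int,
    seed=None,
    eps_p1: float = EPS_P1,
    eps_p2: float = EPS_P2,
) -> FactorState:
    """K-means++ seeding followed by one Lloyd refinement.

    Seeds become candidate centroids, each spectrum is assigned to its
    nearest seed (binary memberships), and the centroids are recomputed as
    cluster means.  Deterministic given ``seed``.
    """
    X = data.X if isinstance(data, HyperspectralData) else np.asarray(data)
    M = X.shape[0]
    if n_clusters > M:
        raise ValueError("n_clusters cannot exceed the number of spectra")
    rng = np.random.RandomState(
        np.random.default_rng(seed).integers(2**31 - 1)
    )
    seeds, _ = kmeans_plusplus(X, n_clusters, random_state=rng)
    d2 = ((X[:, None, :] - seeds[None, :, :]) ** 2).sum(axis=2)
    assign = np.argmin(d2, axis=1)
    U = np.zeros((M, n_clusters))
    U[np.arange(M), assign] = 1.0
    V = seeds.copy()
    for k in range(n_clusters):
        members = assign == k
        if members.any():
            V[k] = X[members].mean(axis=0)
    U, V = _normalize_columns(U, V)
    return FactorState(
        U=clip_positive(U, eps_p1, eps_p2),
        V=clip_positive(V, eps_p1, eps_p2),
    )


def init_svd(
    data: HyperspectralData | np.ndarray,
    n_clusters: int,
    eps_p1: float = EPS_P1,
    eps_p2: float = EPS_P2,
) -> FactorState:
    """Nonnegative double SVD (NNDSVD-family) initialization; deterministic.

    For each of the leading K singular triplets the positive or negative
    part pair with the larger contribution is kept, scaled by the singular
    value.  Output is strictly positive after clipping.
    """
    X = data.X if isinstance(data, HyperspectralData) else np.asarray(data)
    M, N = X.shape
    if n_clusters > min(M, N):
        raise ValueError("n_clusters cannot exceed min(M, N)")
    # dense truncated SVD; data sizes here are desk scale
    left, sing, right_t = np.linalg.svd(X, full_matrices=False)
    U = np.zeros((M, n_clusters))
    V = np.zeros((n_clusters, N))
    # leading component of a nonnegative matrix is sign-fixable to >= 0
    U[:, 0] = np.sqrt(sing[0]) * np.abs(left[:, 0])
    V[0, :] = np.sqrt(sing[0]) * np.abs(right_t[0, :])
    for k in range(1, n_clusters):
        u, v = left[:, k], right_t[k, :]
        up, un = np.maximum(u, 0), np.maximum(-u, 0)
        vp, vn = np.maximum(v, 0), np.maximum(-v, 0)
        pos = np.linalg.norm(up) * np.linalg.norm(vp)
        neg = np.linalg.norm(un) * np.linalg.norm(vn)
        if pos >= neg:
            norm_u, norm_v, weight = up, vp, pos
        else:
            norm_u, norm_v, weight = un, vn, neg
        if weight > 0:
            scale = np.sqrt(sing[k] * weight)
            U[:, k] = scale * norm_u / np.linalg.norm(norm_u)
            V[k, :] = scale * norm_v / np.linalg.norm(norm_v)
        else:  # degenerate component: fall back to a flat positive vector
            U[:, k] = np.sqrt(sing[k] / M)
            V[k, :] = np.sqrt(sing[k] / N)
    U, V = _normalize_columns(U, V)
    return FactorState(
        U=clip_positive(U, eps_p1, eps_p2),
        V=clip_positive(V, eps_p1, eps_p2),
    )


def initialize(
    data,
    n_clusters: int,
    method: str = "svd",
    seed=None,
    eps_p1: float = EPS_P1,
    eps_p2: float = EPS_P2,
) -> FactorState:
    """Dispatch to ``init_svd`` or ``init_kmeanspp`` by name."""
    if method == "svd":
        return init_svd(data, n_clusters, eps_p1=eps_p1, eps_p2=eps_p2)
    if method in ("kmeans++", "kmeanspp"):
        return init_kmeanspp(
            data, n_clusters, seed=seed, eps_p1=eps_p1, eps_p2=eps_p2
        )
    raise ValueError(f"unknown initialization method {method!r}")
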