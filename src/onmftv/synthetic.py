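"""Synthetic hyperspectral phantoms with spatially coherent label regions.

The generator emulates the statistical structure of an annotated mass-
spectrometry-imaging section: K spatially connected tissue-like regions on a
2-D pixel grid, one nonnegative characteristic spectrum per region (a
dominant disjoint channel block riding on a shared baseline), additive
nonnegative noise, and optionally an irregular mask of non-annotated pixels.

Default shape: a 40×40 grid with K = 6 classes (one deliberately shrunk to a
~2% minority, mirroring a strongly underrepresented cell class) and N = 120
channels.  The noise level is controlled through ``snr``, defined as the
target ratio ``||U* V*||_F / ||noise||_F``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import HyperspectralData, clip_positive
from .grid import SpatialGrid

__all__ = ["Phantom", "make_phantom", "class_imbalance"]


@dataclass
class Phantom:
    """A generated dataset plus its ground-truth factors."""

    data: HyperspectralData
    U_true: np.ndarray  # (M, K) binary, one 1 per row
    V_true: np.ndarray  # (K, N) nonnegative signatures
    labels: np.ndarray  # (M,) in {0..K-1}


def _grow_regions(height, width, n_regions, rng, weights=None):
    """Multi-source randomized BFS growth => connected label regions.

    ``weights`` optionally biases how often each region gets to claim the
    next pixel, which controls the expected region sizes.
    """
    n_pix = height * width
    if n_regions > n_pix:
        raise ValueError("more regions than pixels")
    labels = -np.ones((height, width), dtype=np.int64)
    seeds = rng.choice(n_pix, size=n_regions, replace=False)
    frontiers = []
    for k, s in enumerate(seeds):
        i, j = divmod(int(s), width)
        labels[i, j] = k
        frontiers.append([(i, j)])
    if weights is None:
        weights = np.ones(n_regions)
    weights = np.asarray(weights, dtype=float)
    n_assigned = n_regions
    while n_assigned < n_pix:
        active = [k for k in range(n_regions) if frontiers[k]]
        w = weights[active]
        k = active[rng.choice(len(active), p=w / w.sum())]
        # pop a random frontier pixel and try to claim an unlabeled neighbor
        idx = rng.integers(len(frontiers[k]))
        i, j = frontiers[k][idx]
        free = [
            (i + di, j + dj)
            for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1))
            if 0 <= i + di < height and 0 <= j + dj < width
            and labels[i + di, j + dj] < 0
        ]
        if not free:
            frontiers[k].pop(idx)
            continue
        ni, nj = free[rng.integers(len(free))]
        labels[ni, nj] = k
        frontiers[k].append((ni, nj))
        n_assigned += 1
    return labels


def _signatures(n_clusters, n_channels, rng, baseline=0.1, amplitude=1.0):
    """K nonnegative spectra with disjoint dominant channel blocks."""
    V = baseline * rng.uniform(0.5, 1.5, size=(n_clusters, n_channels))
    block = n_channels // n_clusters
    for k in range(n_clusters):
        lo, hi = k * block, (k + 1) * block if k < n_clusters - 1 else n_channels
        V[k, lo:hi] += amplitude * rng.uniform(0.8, 1.2, size=hi - lo)
    return V


def make_phantom(
    height: int = 40,
    width: int = 40,
    n_clusters: int = 6,
    n_channels: int = 120,
    snr: float = 3.0,
    mask_fraction: float = 0.0,
    minority_fraction: float | None = 0.02,
    contamination: float = 0.1,
    noise: str = "gaussian",
    seed=None,
) -> Phantom:
    """Generate a spatially coherent phantom with known factors.

    Parameters
    ----------
    snr : float
        Target ``||signal||_F / ||noise||_F``; ``np.inf`` gives noise-free
        data (``X = U* V*`` exactly, contamination included off).
    mask_fraction : float
        Fraction of pixels blanked out (dropped from the dataset) to mimic
        non-annotated holes in the acquisition mask.
    minority_fraction : float or None
        If set, one region is grown with a weight that targets roughly this
        share of the pixels, reproducing a strongly underrepresented class.
        ``None`` grows all regions with equal weight.
    contamination : float
        Fraction of pixels whose spectrum is a convex mixture of the own
        and one other class signature (mixing weight U(0.3, 0.8)).  Models
        spot-level spectral mixing — matrix-application artifacts and
        partial-volume effects — which is what makes a purely feature-space
        clustering of real acquisitions spatially incoherent.
    noise : {"gaussian", "poisson"}
        Truncated-Gaussian (default, matching a Frobenius discrepancy) or
        Poisson-like counting noise.
    """
    if n_clusters < 1:
        raise ValueError("n_clusters must be >= 1")
    if n_channels < n_clusters:
        raise ValueError("need at least one channel per cluster")
    rng = np.random.default_rng(seed)
    weights = None
    if minority_fraction is not None and n_clusters > 1:
        weights = np.ones(n_clusters)
        # growth share is roughly proportional to the claim weight
        weights[0] = minority_fraction * n_clusters / (1 - minority_fraction)
    label_img = _grow_regions(height, width, n_clusters, rng, weights)

    keep = np.ones(height * width, dtype=bool)
    if mask_fraction > 0:
        n_drop = int(round(mask_fraction * height * width))
        drop = rng.choice(height * width, size=n_drop, replace=False)
        keep[drop] = False

    ii, jj = np.meshgrid(np.arange(height), np.arange(width), indexing="ij")
    coords = np.column_stack([ii.ravel(), jj.ravel()])[keep]
    labels = label_img.ravel()[keep]
    M = coords.shape[0]

    U_true = np.zeros((M, n_clusters))
    U_true[np.arange(M), labels] = 1.0
    V_true = _signatures(n_clusters, n_channels, rng)
    signal = U_true @ V_true

    if not np.isinf(snr) and contamination > 0 and n_clusters > 1:
        n_bad = int(round(contamination * M))
        bad = rng.choice(M, size=n_bad, replace=False)
        other = (labels[bad] + rng.integers(1, n_clusters, size=n_bad)) % n_clusters
        mix = rng.uniform(0.3, 0.8, size=n_bad)[:, None]
        signal = signal.copy()
        signal[bad] = (1.0 - mix) * V_true[labels[bad]] + mix * V_true[other]

    if np.isinf(snr):
        X = signal.copy()
    elif noise == "gaussian":
        raw = rng.standard_normal(signal.shape)
        raw = np.maximum(raw, 0.0)  # truncated: nonnegative additive noise
        scale = np.linalg.norm(signal) / (snr * np.linalg.norm(raw))
        X = signal + scale * raw
    elif noise == "poisson":
        # counting noise whose Frobenius deviation matches the snr target
        lam = snr**2 * signal / signal.mean()
        counts = rng.poisson(lam).astype(float)
        X = counts * signal.mean() / snr**2
        X = np.maximum(X, 0.0)
    else:
        raise ValueError(f"unknown noise model {noise!r}")

    grid = SpatialGrid(coords)
    data = HyperspectralData(X=clip_positive(X), grid=grid, labels=labels)
    return Phantom(data=data, U_true=U_true, V_true=V_true, labels=labels)


def class_imbalance(
    phantom: Phantom, minority_fraction: float, seed=None
) -> Phantom:
    """Shrink one region to ``minority_fraction`` of the pixels.

    Pixels peeled off the minority region (always region 0) are absorbed by
    adjacent regions via boundary erosion, preserving 4-connectivity of the
    remaining minority pixels.  Stresses the empty-cluster failure mode of
    strongly TV-regularized solvers.
    """
    K = phantom.V_true.shape[0]
    if not 0 < minority_fraction <= 1.0 / K:
        raise ValueError("minority_fraction must be in (0, 1/K]")
    rng = np.random.default_rng(seed)
    grid = phantom.data.grid
    labels = phantom.labels.copy()
    target = max(1, int(round(minority_fraction * len(labels))))
    minority = 0
    # undirected adjacency from the grid's forward edges
    nbrs: list[list[int]] = [[] for _ in range(len(labels))]
    for s, t in zip(grid.edge_src, grid.edge_tgt):
        nbrs[s].append(int(t))
        nbrs[t].append(int(s))
    current = int((labels == minority).sum())
    while current > target:
        boundary = [
            m
            for m in np.flatnonzero(labels == minority)
            if any(labels[q] != minority for q in nbrs[m])
        ]
        # peel a boundary pixel that keeps the remainder connected
        rng.shuffle(boundary)
        peeled = False
        for m in boundary:
            rest = np.flatnonzero(labels == minority)
            rest = rest[rest != m]
            if len(rest) == 0 or _is_connected(rest, nbrs):
                other = [labels[q] for q in nbrs[m] if labels[q] != minority]
                labels[m] = other[rng.integers(len(other))]
                current -= 1
                peeled = True
                break
        if not peeled:
            raise ValueError("cannot shrink region without disconnecting it")
    M = len(labels)
    U_true = np.zeros((M, K))
    U_true[np.arange(M), labels] = 1.0
    X = U_true @ phantom.V_true + (
        phantom.data.X - phantom.U_true @ phantom.V_true
    )
    data = HyperspectralData(
        X=clip_positive(X), grid=grid, labels=labels
    )
    return Phantom(
        data=data, U_true=U_true, V_true=phantom.V_true, labels=labels
    )


def _is_connected(members: np.ndarray, nbrs) -> bool:
    member_set = set(int(m) for m in members)
    start = next(iter(member_set))
    seen = {start}
    stack = [start]
    while stack:
        m = stack.pop()
        for q in nbrs[m]:
            if q in member_set and q not in seen:
                seen.add(q)
                stack.append(q)
    return len(seen) == len(member_set)
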