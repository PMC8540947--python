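"""Hard-clustering extraction and external cluster validation measures.

Given a predicted partition and ground-truth classes, the measures are
computed from the K_pred × K_true contingency table ``n_kk̃`` (number of
points in predicted cluster k drawn from true class k̃) and its derived
probabilities ``p_kk̃ = n_kk̃ / n``, ``p_k`` (row marginals), ``p̃_k̃``
(column marginals):

* Entropy ``E = -sum_k p_k sum_k̃ (p_kk̃/p_k) log(p_kk̃/p_k)``, range
  ``[0, log K]``;
* normalized Variation of Information
  ``VI_n = 1 + 2 MI / (sum_k p_k log p_k + sum_k̃ p̃_k̃ log p̃_k̃)``,
  range ``[0, 1]``;
* normalized van Dongen criterion
  ``VD_n = (2n - sum_k max_k̃ n_kk̃ - sum_k̃ max_k n_kk̃)
           / (2n - max_k n_k· - max_k̃ n_·k̃)``, range ``[0, 1]``.

Lower is better for all three; 0 means the partitions coincide (up to
relabeling).  Empty predicted clusters contribute zero rows and are handled
gracefully — this is why these measures are preferred over purity for
solvers that may empty out a cluster.  Natural logarithms throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import Clustering

__all__ = [
    "ContingencyTable",
    "hard_clustering",
    "contingency",
    "entropy",
    "vi_normalized",
    "vd_normalized",
    "evaluate_clustering",
]


@dataclass
class ContingencyTable:
    """Counts ``n_kk̃`` between predicted clusters (rows) and true classes."""

    counts: np.ndarray

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2:
            raise ValueError("contingency counts must be 2-D")
        if np.any(self.counts < 0):
            raise ValueError("contingency counts must be nonnegative")

    @property
    def n(self) -> int:
        return int(self.counts.sum())

    @property
    def row_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def col_marginals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def p(self) -> np.ndarray:
        return self.counts / self.n


def hard_clustering(U, seed=None) -> Clustering:
    """Assign each spectrum to the column of its row maximum.

    Exact ties (including all-zero rows, which tie across all columns) are
    broken by a uniform random choice driven by ``seed`` so replicates are
    reproducible.
    """
    U = np.asarray(U, dtype=float)
    if U.ndim != 2:
        raise ValueError("U must be an (M, K) matrix")
    M, K = U.shape
    row_max = U.max(axis=1, keepdims=True)
    labels = np.argmax(U, axis=1)
    is_tie = (U == row_max).sum(axis=1) > 1
    if np.any(is_tie):
        rng = np.random.default_rng(seed)
        for m in np.flatnonzero(is_tie):
            labels[m] = rng.choice(np.flatnonzero(U[m] == row_max[m, 0]))
    return Clustering(labels=labels, n_clusters=K, source_U=U)


def contingency(pred, truth, n_clusters: int | None = None) -> ContingencyTable:
    """Contingency table between predicted labels and true classes.

    ``pred`` may be a :class:`Clustering` or a label vector.  Predicted
    clusters without points yield all-zero rows.
    """
    if isinstance(pred, Clustering):
        labels, K = pred.labels, pred.n_clusters
    else:
        labels = np.asarray(pred)
        K = n_clusters or int(labels.max()) + 1
    truth = np.asarray(truth)
    if labels.shape[0] != truth.shape[0]:
        raise ValueError("predicted and true label vectors differ in length")
    true_ids, true_codes = np.unique(truth, return_inverse=True)
    counts = np.zeros((K, len(true_ids)), dtype=np.int64)
    np.add.at(counts, (labels, true_codes), 1)
    return ContingencyTable(counts)


def _xlogy(x, y):
    """``x * log(y)`` with the convention ``0 * log 0 = 0``."""
    out = np.zeros_like(np.asarray(x, dtype=float))
    mask = np.asarray(x) > 0
    out[mask] = np.asarray(x, dtype=float)[mask] * np.log(
        np.asarray(y, dtype=float)[mask]
    )
    return out


def entropy(table: ContingencyTable) -> float:
    """Conditional entropy of the true classes within each predicted cluster."""
    if table.n == 0:
        raise ValueError("empty contingency table")
    p = table.p
    pk = p.sum(axis=1, keepdims=True)
    # rows with pk == 0 (empty clusters) contribute nothing
    with np.errstate(divide="ignore", invalid="ignore"):
        cond = np.where(pk > 0, p / np.where(pk > 0, pk, 1.0), 0.0)
    return float(-np.sum(_xlogy(p, cond)))


def vi_normalized(table: ContingencyTable) -> float:
    """Normalized variation of information ``1 + 2 MI / (−H_pred − H_true)``."""
    if table.n == 0:
        raise ValueError("empty contingency table")
    p = table.p
    pk = p.sum(axis=1)
    pt = p.sum(axis=0)
    denom = float(np.sum(_xlogy(pk, pk)) + np.sum(_xlogy(pt, pt)))
    if denom == 0.0:
        # both partitions trivial: perfect agreement by convention
        return 0.0
    outer = pk[:, None] * pt[None, :]
    mi = float(np.sum(_xlogy(p, np.where(p > 0, p / np.where(outer > 0, outer, 1.0), 1.0))))
    return 1.0 + 2.0 * mi / denom


def vd_normalized(table: ContingencyTable) -> float:
    """Normalized van Dongen criterion (0 = perfect, 1 = uninformative)."""
    if table.n == 0:
        raise ValueError("empty contingency table")
    n = table.n
    num = 2 * n - table.counts.max(axis=1).sum() - table.counts.max(axis=0).sum()
    den = 2 * n - table.row_marginals.max() - table.col_marginals.max()
    if den == 0:
        return 0.0
    return float(num) / float(den)


def evaluate_clustering(pred, truth, n_clusters: int | None = None) -> dict:
    """All three measures for a predicted partition against ground truth."""
    table = contingency(pred, truth, n_clusters=n_clusters)
    return {
        "entropy": entropy(table),
        "vi_n": vi_normalized(table),
        "vd_n": vd_normalized(table),
        "K_used": table.counts.shape[0],
    }
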