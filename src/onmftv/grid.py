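"""Pixel grids and neighborhood structure for spatially resolved spectra.

Every spectrum (row of the data matrix) sits on an integer 2-D pixel
position.  Total-variation terms couple each pixel ``m`` to its forward
neighbors ``N_m`` (the pixel below and the pixel to the right, restricted to
occupied positions), which yields a one-sided estimate of both gradient
components.  The *adjoint* neighborhood ``N̄_m`` is the transpose relation:
``m̃ ∈ N̄_m  ⇔  m ∈ N_m̃``.

Irregular masks (e.g. only annotated pixels of a tissue slide) are supported
by simply dropping neighbors that fall outside the occupied set; TV terms
then have fewer summands.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

__all__ = ["SpatialGrid", "build_grid", "neighbors"]


class SpatialGrid:
    """Occupied pixel positions plus the forward-difference edge structure.

    Parameters
    ----------
    coords : array-like of shape (M, 2)
        Integer (row, col) position of each spectrum, 0-based.  One spectrum
        per pixel; duplicates are rejected.

    Attributes
    ----------
    coords : ndarray of shape (M, 2)
        The validated coordinates, in input order (rows of the data matrix
        align index-wise with this order).
    n_pixels : int
        Number of occupied pixels M.
    height, width : int
        Grid extents (max coordinate + 1).
    edge_src, edge_tgt : ndarray of shape (E,)
        Directed edges of the forward stencil: for each pixel ``m`` and each
        occupied neighbor in ``N_m`` there is one edge ``m -> m̃``.
    diff_matrix : scipy.sparse.csr_matrix of shape (E, M)
        Sparse forward-difference operator ``D`` with ``+1`` at the source
        and ``-1`` at the target of each edge, so ``(D u)_e = u_src - u_tgt``.
    """

    def __init__(self, coords):
        coords = np.asarray(coords, dtype=np.int64)
        if coords.ndim != 2 or coords.shape[1] != 2 or coords.shape[0] == 0:
            raise ValueError("coords must be a non-empty (M, 2) integer array")
        if np.any(coords < 0):
            raise ValueError("coords must be nonnegative (0-based row, col)")
        pos_to_idx: dict[tuple[int, int], int] = {}
        for idx, (i, j) in enumerate(coords):
            key = (int(i), int(j))
            if key in pos_to_idx:
                raise ValueError(f"duplicate pixel coordinate {key}")
            pos_to_idx[key] = idx
        self.coords = coords
        self.n_pixels = coords.shape[0]
        self.height = int(coords[:, 0].max()) + 1
        self.width = int(coords[:, 1].max()) + 1
        self._pos_to_idx = pos_to_idx

        src, tgt = [], []
        for idx, (i, j) in enumerate(coords):
            for di, dj in ((1, 0), (0, 1)):
                nb = pos_to_idx.get((int(i) + di, int(j) + dj))
                if nb is not None:
                    src.append(idx)
                    tgt.append(nb)
        self.edge_src = np.asarray(src, dtype=np.int64)
        self.edge_tgt = np.asarray(tgt, dtype=np.int64)
        E = len(src)
        data = np.concatenate([np.ones(E), -np.ones(E)])
        rows = np.concatenate([np.arange(E), np.arange(E)])
        cols = np.concatenate([self.edge_src, self.edge_tgt])
        self.diff_matrix = sp.csr_matrix(
            (data, (rows, cols)), shape=(E, self.n_pixels)
        )

    @property
    def n_edges(self) -> int:
        return len(self.edge_src)

    def neighbors(self, m: int) -> set[int]:
        """Forward neighborhood ``N_m`` as a set of spectrum indices."""
        self._check_index(m)
        return set(self.edge_tgt[self.edge_src == m].tolist())

    def adjoint_neighbors(self, m: int) -> set[int]:
        """Adjoint neighborhood ``N̄_m = {m̃ : m ∈ N_m̃}``."""
        self._check_index(m)
        return set(self.edge_src[self.edge_tgt == m].tolist())

    def out_degree(self) -> np.ndarray:
        """``|N_m|`` for every pixel, shape (M,)."""
        return np.bincount(self.edge_src, minlength=self.n_pixels)

    def in_degree(self) -> np.ndarray:
        """``|N̄_m|`` for every pixel, shape (M,)."""
        return np.bincount(self.edge_tgt, minlength=self.n_pixels)

    def incidence(self) -> sp.csr_matrix:
        """Boolean neighbor relation as an M×M sparse matrix."""
        return sp.csr_matrix(
            (np.ones(self.n_edges), (self.edge_src, self.edge_tgt)),
            shape=(self.n_pixels, self.n_pixels),
        )

    def _check_index(self, m: int) -> None:
        if not 0 <= m < self.n_pixels:
            raise IndexError(
                f"spectrum index {m} out of range [0, {self.n_pixels})"
            )

    @classmethod
    def full(cls, height: int, width: int) -> "SpatialGrid":
        """Fully occupied ``height × width`` grid in raster (row-major) order."""
        ii, jj = np.meshgrid(
            np.arange(height), np.arange(width), indexing="ij"
        )
        return cls(np.column_stack([ii.ravel(), jj.ravel()]))

    def label_image(self, values, fill=np.nan) -> np.ndarray:
        """Scatter a per-spectrum vector onto the (height, width) image plane."""
        values = np.asarray(values)
        img = np.full((self.height, self.width), fill, dtype=float)
        img[self.coords[:, 0], self.coords[:, 1]] = values
        return img

    def __repr__(self) -> str:  # pragma: no cover
        return (
            f"SpatialGrid(n_pixels={self.n_pixels}, "
            f"extent={self.height}x{self.width}, n_edges={self.n_edges})"
        )


def build_grid(coords) -> SpatialGrid:
    """Build a :class:`SpatialGrid` from integer (row, col) pairs."""
    return SpatialGrid(coords)


def neighbors(grid: SpatialGrid, m: int) -> set[int]:
    """Forward neighborhood ``N_m`` of spectrum ``m`` on ``grid``."""
    return grid.neighbors(m)
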