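"""Core containers: hyperspectral data bound to a grid, factor state, clustering.

The data matrix ``X`` holds one spectrum per row (M spectra × N channels,
nonnegative intensities).  Row ``m`` of ``X`` corresponds to pixel
``grid.coords[m]``.  On ingestion every entry is clipped to the interval
``[eps_p1, eps_p2]`` (defaults 1e-16 and 1e35) — the same element-wise
projection the solvers use to avoid zero locking and overflow in
multiplicative updates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import SpatialGrid

__all__ = [
    "EPS_P1",
    "EPS_P2",
    "clip_positive",
    "HyperspectralData",
    "FactorState",
    "Clustering",
    "ingest",
    "load_matrix",
    "load_coords",
    "load_labels",
]

#: Lower clipping bound for the element-wise positivity projection.
EPS_P1 = 1e-16
#: Upper clipping bound guarding against overflow.
EPS_P2 = 1e35


def clip_positive(A, eps_p1: float = EPS_P1, eps_p2: float = EPS_P2):
    """Element-wise projection ``a -> max(min(a, eps_p2), eps_p1)``.

    Idempotent; keeps multiplicative iterates strictly positive (no zero
    locking) and bounded.
    """
    return np.clip(np.asarray(A, dtype=float), eps_p1, eps_p2)


@dataclass
class HyperspectralData:
    """Nonnegative spectra bound to pixel positions, with optional labels."""

    X: np.ndarray
    grid: SpatialGrid
    labels: np.ndarray | None = None

    @property
    def n_spectra(self) -> int:
        return self.X.shape[0]

    @property
    def n_channels(self) -> int:
        return self.X.shape[1]


@dataclass
class FactorState:
    """Factor matrices of an (O)NMF iteration.

    U : (M, K) nonnegative cluster membership matrix.
    V : (K, N) nonnegative centroid (characteristic spectra) matrix.
    W : optional (M, K) auxiliary matrix used by solvers that split the
        quartic orthogonality penalty.
    """

    U: np.ndarray
    V: np.ndarray
    W: np.ndarray | None = None
    iteration: int = 0
    cost_trace: list[float] = field(default_factory=list)

    @property
    def n_clusters(self) -> int:
        return self.U.shape[1]


@dataclass
class Clustering:
    """Hard partition of the spectra plus the soft membership it came from."""

    labels: np.ndarray
    n_clusters: int
    source_U: np.ndarray | None = None


def ingest(
    X,
    grid: SpatialGrid,
    eps_p1: float = EPS_P1,
    eps_p2: float = EPS_P2,
    labels=None,
) -> HyperspectralData:
    """Validate and positivity-project a raw matrix into a dataset.

    Raises on shape mismatch with the grid and on non-finite entries.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("X must be a 2-D matrix (spectra x channels)")
    if X.shape[0] != grid.n_pixels:
        raise ValueError(
            f"X has {X.shape[0]} rows but the grid has {grid.n_pixels} "
            "occupied pixels"
        )
    if not np.all(np.isfinite(X)):
        raise ValueError("X contains non-finite entries")
    if labels is not None:
        labels = np.asarray(labels)
        if labels.shape[0] != X.shape[0]:
            raise ValueError("labels length must match the number of spectra")
    return HyperspectralData(
        X=clip_positive(X, eps_p1, eps_p2), grid=grid, labels=labels
    )


# ---------------------------------------------------------------------------
# File ingestion (CSV/TSV or HDF5)
# ---------------------------------------------------------------------------

def load_matrix(path: str, dataset: str = "X") -> np.ndarray:
    """Read a spectra × channels matrix from CSV/TSV or an HDF5 dataset."""
    path = str(path)
    if path.endswith((".h5", ".hdf5")):
        import h5py

        with h5py.File(path, "r") as fh:
            return np.asarray(fh[dataset], dtype=float)
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, header=None).to_numpy(dtype=float)


def load_coords(path: str) -> np.ndarray:
    """Read a two-column integer (row, col) coordinate table, row-aligned."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    coords = pd.read_csv(path, sep=sep, header=None).to_numpy()
    if coords.shape[1] != 2:
        raise ValueError("coordinate file must have exactly two columns")
    return coords.astype(np.int64)


def load_labels(path: str) -> np.ndarray:
    """Read a one-column class label vector."""
    sep = "\t" if str(path).endswith((".tsv", ".txt")) else ","
    return pd.read_csv(path, sep=sep, header=None).to_numpy().ravel()
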