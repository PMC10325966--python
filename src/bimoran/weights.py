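"""Spatial proximity matrices.

All statistics in this package localize spot-spot comparisons through an
n x n non-negative weight matrix normalized so that its total mass equals n
(so a "flat" matrix would give each ordered spot pair weight 1/n). Two
constructions are provided:

* an RBF (Gaussian) kernel on Euclidean distance, with a hard cutoff on the
  unnormalized kernel value, suited to secreted signalling over one-to-few
  spot diameters;
* a directed k-nearest-neighbour adjacency for contact/ECM signalling that
  only reaches immediately adjacent cells.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy.io import mmwrite
from scipy.spatial.distance import cdist
from sklearn.neighbors import NearestNeighbors

#: above this spot count matrices are stored sparse
DENSE_LIMIT = 5000

#: brute-force KNN (stable, index-ordered tie-break) limit
_KNN_BRUTE_LIMIT = 4096


@dataclass
class SpatialWeights:
    """Normalized spot-spot proximity matrix plus construction parameters."""

    w: np.ndarray | sp.spmatrix
    kind: str
    l: float | None = None
    cutoff: float | None = None
    n_neighbors: int | None = None
    single_cell: bool = False

    def __post_init__(self) -> None:
        if sp.issparse(self.w):
            self.w = self.w.tocsr()
            if (self.w.data < 0).any():
                raise ValueError("weights contain negative entries")
            if np.isnan(self.w.data).any():
                raise ValueError("weights contain NaN")
        else:
            self.w = np.asarray(self.w, dtype=float)
            if (self.w < 0).any():
                raise ValueError("weights contain negative entries")
            if np.isnan(self.w).any():
                raise ValueError("weights contain NaN")
        if self.w.shape[0] != self.w.shape[1]:
            raise ValueError("weight matrix must be square")

    @property
    def n(self) -> int:
        return self.w.shape[0]

    @property
    def is_sparse(self) -> bool:
        return sp.issparse(self.w)

    @property
    def total(self) -> float:
        return float(self.w.sum())

    @property
    def row_sums(self) -> np.ndarray:
        return np.asarray(self.w.sum(axis=1)).ravel()

    @property
    def col_sums(self) -> np.ndarray:
        return np.asarray(self.w.sum(axis=0)).ravel()

    @property
    def diagonal(self) -> np.ndarray:
        return np.asarray(self.w.diagonal()).ravel()

    @property
    def sq_sum(self) -> float:
        """Sum of squared entries."""
        if self.is_sparse:
            return float((self.w.data**2).sum())
        return float((self.w**2).sum())

    @property
    def row_sq_sums(self) -> np.ndarray:
        """Per-row sum of squared entries."""
        if self.is_sparse:
            return np.asarray(self.w.multiply(self.w).sum(axis=1)).ravel()
        return (self.w**2).sum(axis=1)

    def dot(self, v: np.ndarray) -> np.ndarray:
        """``W @ v`` (columns of v treated independently)."""
        return np.asarray(self.w @ v)

    def tdot(self, v: np.ndarray) -> np.ndarray:
        """``W.T @ v``."""
        return np.asarray(self.w.T @ v)

    def toarray(self) -> np.ndarray:
        return self.w.toarray() if self.is_sparse else self.w

    def write_mm(self, path) -> None:
        """Dump the matrix as MatrixMarket for inspection."""
        mmwrite(str(path), sp.coo_matrix(self.w))


def _normalize(w0, n: int, kind: str, **params) -> SpatialWeights:
    total = float(w0.sum())
    if total <= 0:
        raise ValueError("cutoff removes all neighbours (weight matrix is all zero)")
    return SpatialWeights(w=w0 * (n / total), kind=kind, **params)


def build_rbf_weights(
    coords: np.ndarray,
    l: float,
    cutoff: float = 0.0,
    single_cell: bool = False,
) -> SpatialWeights:
    """RBF kernel weights: ``w0_ij = exp(-d_ij^2 / (2 l^2))``.

    Entries with unnormalized kernel value strictly below ``cutoff`` are
    zeroed, which restricts support to distances
    ``d <= l * sqrt(-2 ln cutoff)``. With ``single_cell=True`` the diagonal
    is zeroed to remove self-pairs (auto-correlation) at single-cell
    resolution. The surviving matrix is rescaled to total mass n.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n < 2:
        raise ValueError("need at least 2 spots")
    if l <= 0:
        raise ValueError("length scale l must be positive")
    if not 0 <= cutoff < 1:
        raise ValueError("cutoff must be in [0, 1)")

    if n <= DENSE_LIMIT or cutoff <= 0:
        d2 = cdist(coords, coords, "sqeuclidean")
        w0 = np.exp(-d2 / (2 * l * l))
        if cutoff > 0:
            w0[w0 < cutoff] = 0.0
        if single_cell:
            np.fill_diagonal(w0, 0.0)
    else:
        # sparse path: the cutoff bounds the support radius
        radius = l * np.sqrt(-2.0 * np.log(cutoff))
        nn = NearestNeighbors(radius=radius).fit(coords)
        graph = nn.radius_neighbors_graph(coords, mode="distance")
        graph = graph.tocoo()
        off = graph.row != graph.col  # sklearn drops the 0-distance diagonal anyway
        row, col, dist = graph.row[off], graph.col[off], graph.data[off]
        data = np.exp(-dist**2 / (2 * l * l))
        keep = data >= cutoff
        w0 = sp.coo_matrix((data[keep], (row[keep], col[keep])), shape=(n, n)).tocsr()
        if not single_cell:
            w0 = w0 + sp.identity(n, format="csr")
        w0.eliminate_zeros()
    return _normalize(w0, n, kind="rbf", l=l, cutoff=cutoff, single_cell=single_cell)


def build_knn_weights(
    coords: np.ndarray,
    n_neighbors: int = 6,
    symmetrize: bool = False,
) -> SpatialWeights:
    """Directed k-nearest-neighbour adjacency, normalized to total mass n.

    Each row has exactly ``n_neighbors`` unit entries before normalization
    (self excluded). Distance ties at the k-th neighbour are broken by spot
    index order, so the construction is deterministic. The adjacency is
    directed (i -> its neighbours); ``symmetrize=True`` takes the
    elementwise maximum with the transpose before normalization.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if n_neighbors < 1:
        raise ValueError("n_neighbors must be positive")
    if n <= n_neighbors:
        raise ValueError(f"need more than n_neighbors={n_neighbors} spots, got {n}")

    if n <= _KNN_BRUTE_LIMIT:
        d = cdist(coords, coords)
        np.fill_diagonal(d, np.inf)
        # stable sort => equal distances ranked by spot index
        order = np.argsort(d, axis=1, kind="stable")[:, :n_neighbors]
        w0 = np.zeros((n, n))
        rows = np.repeat(np.arange(n), n_neighbors)
        w0[rows, order.ravel()] = 1.0
    else:
        nn = NearestNeighbors(n_neighbors=n_neighbors + 1).fit(coords)
        _, idx = nn.kneighbors(coords)
        w0 = sp.lil_matrix((n, n))
        for i in range(n):
            neigh = [j for j in idx[i] if j != i][:n_neighbors]
            w0[i, neigh] = 1.0
        w0 = w0.tocsr()
    if symmetrize:
        if sp.issparse(w0):
            w0 = w0.maximum(w0.T)
        else:
            w0 = np.maximum(w0, w0.T)
    return _normalize(
        w0, n, kind="knn", n_neighbors=n_neighbors, single_cell=True
    )
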