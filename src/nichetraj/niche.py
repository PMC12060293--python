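"""Per-sample niche graphs from cell coordinates and type labels.

A niche is anchored at one cell and contains that cell plus its k nearest
neighbors (Euclidean distance, default k = 50).  Niches are connected when
their anchoring cells are mutual k-nearest neighbors, giving a symmetric
binary adjacency A.  Each cell i is associated with every niche j it
belongs to through the Gaussian kernel

    w_ij = exp(-d_ij^2 / sigma_j^2),

where d_ij is the distance from cell i to anchor j and sigma_j is the
distance from anchor j to its 20th nearest neighbor.  A niche's cell-type
composition vector v_j is the w-weighted fraction of each type among its
members; rows of the composition matrix V sum to 1.

Graphs are always built per sample: no niche, edge or weight ever crosses
sample boundaries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse

__all__ = [
    "NicheGraph",
    "build_knn",
    "build_niche_adjacency",
    "cell_niche_weights",
    "composition_vectors",
    "normalize_adjacency",
    "build_niche_graph",
    "build_niche_graphs",
]


@dataclass
class NicheGraph:
    """One sample's niche network.

    Attributes
    ----------
    sample : str
        Sample identifier.
    cell_ids : ndarray of str, shape (N,)
        Anchoring-cell (= niche) identifiers.
    adjacency : scipy.sparse.csr_matrix, shape (N, N)
        Symmetric binary mutual-kNN adjacency, zero diagonal.
    weights : scipy.sparse.csr_matrix, shape (N, N)
        Cell-niche association scores; entry (i, j) is w_ij for member
        cells only (sparse contract), with w_jj = 1 for each anchor.
    composition : ndarray, shape (N, M)
        Row-stochastic cell-type composition matrix V.
    sigma : ndarray, shape (N,)
        Per-niche Gaussian bandwidths.
    cell_types : pd.Index
        The shared cell-type category order (length M).
    """

    sample: str
    cell_ids: np.ndarray
    adjacency: sparse.csr_matrix
    weights: sparse.csr_matrix
    composition: np.ndarray
    sigma: np.ndarray
    cell_types: pd.Index

    @property
    def n_niches(self) -> int:
        return self.adjacency.shape[0]


def build_knn(coords: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs k-nearest neighbors with deterministic tie-breaking.

    Parameters
    ----------
    coords : (N, D) array of coordinates (D = 2 or 3).
    k : number of neighbors, excluding the cell itself.  If k >= N it is
        clamped to N - 1 with a warning.

    Returns
    -------
    indices : (N, k) int array, neighbor indices by nondecreasing distance;
        ties broken by cell index.
    distances : (N, k) float array of the matching Euclidean distances.
    """
    coords = np.asarray(coords, dtype=float)
    n = coords.shape[0]
    if k < 1:
        raise ValueError(f"k must be a positive integer, got {k}")
    if k >= n:
        warnings.warn(
            f"k={k} >= sample size {n}; clamping to {n - 1}", stacklevel=2
        )
        k = n - 1

    indices = np.empty((n, k), dtype=np.int64)
    distances = np.empty((n, k), dtype=float)
    sq = np.einsum("ij,ij->i", coords, coords)
    chunk = max(1, int(2e7) // max(n, 1))  # bound the pairwise block size
    for start in range(0, n, chunk):
        stop = min(start + chunk, n)
        d2 = sq[start:stop, None] + sq[None, :] - 2.0 * coords[start:stop] @ coords.T
        np.maximum(d2, 0.0, out=d2)
        rows = np.arange(start, stop)
        d2[rows - start, rows] = np.inf  # exclude self
        order = np.argsort(d2, axis=1, kind="stable")[:, :k]  # stable = index ties
        indices[start:stop] = order
        distances[start:stop] = np.sqrt(np.take_along_axis(d2, order, axis=1))
    return indices, distances


def build_niche_adjacency(indices: np.ndarray) -> sparse.csr_matrix:
    """Mutual-kNN adjacency: a_ij = 1 iff j in kNN(i) and i in kNN(j)."""
    n, k = indices.shape
    rows = np.repeat(np.arange(n), k)
    directed = sparse.csr_matrix(
        (np.ones(n * k), (rows, indices.ravel())), shape=(n, n)
    )
    mutual = directed.multiply(directed.T)
    mutual.data[:] = 1.0
    return mutual.tocsr()


def cell_niche_weights(
    indices: np.ndarray,
    distances: np.ndarray,
    sigma_rank: int = 20,
    sigma: np.ndarray | None = None,
) -> tuple[sparse.csr_matrix, np.ndarray]:
    """Gaussian cell-niche association scores and per-niche bandwidths.

    Cell i belongs to niche j when i is anchor j or one of its k nearest
    neighbors; only member pairs get a weight.  sigma_j is the distance
    from anchor j to its ``sigma_rank``-th nearest neighbor (clamped to
    the farthest available neighbor when k < sigma_rank), unless an
    explicit ``sigma`` vector is supplied; a zero sigma is replaced by the
    smallest positive member distance.
    """
    n, k = indices.shape
    if sigma is None:
        sigma = distances[:, min(sigma_rank, k) - 1].copy()
    else:
        sigma = np.asarray(sigma, dtype=float).copy()
    if np.any(sigma <= 0.0):
        for j in np.flatnonzero(sigma <= 0.0):
            positive = distances[j][distances[j] > 0.0]
            if positive.size == 0:
                raise ValueError(
                    f"all neighbors of niche {j} are coincident; sigma undefined"
                )
            sigma[j] = positive[0]

    # entries: the anchor itself (d=0, w=1) plus its k members
    niche_col = np.concatenate([np.arange(n), np.repeat(np.arange(n), k)])
    cell_row = np.concatenate([np.arange(n), indices.ravel()])
    d = np.concatenate([np.zeros(n), distances.ravel()])
    w = np.exp(-(d**2) / sigma[niche_col] ** 2)
    weights = sparse.csr_matrix((w, (cell_row, niche_col)), shape=(n, n))
    return weights, sigma


def composition_vectors(
    weights: sparse.csr_matrix, type_indicator: np.ndarray
) -> np.ndarray:
    """Row-stochastic composition matrix V: v_jm = sum_i w_ij I_im / sum_i w_ij."""
    totals = np.asarray(weights.sum(axis=0)).ravel()
    if np.any(totals <= 0.0):
        raise ValueError("niche with zero total association weight")
    v = (weights.T @ type_indicator) / totals[:, None]
    return np.asarray(v)


def normalize_adjacency(adjacency: sparse.spmatrix) -> sparse.csr_matrix:
    """Symmetric normalization D^{-1/2} A D^{-1/2}; isolated nodes get zero rows."""
    degree = np.asarray(adjacency.sum(axis=1)).ravel()
    with np.errstate(divide="ignore"):
        inv_sqrt = 1.0 / np.sqrt(degree)
    inv_sqrt[~np.isfinite(inv_sqrt)] = 0.0
    d = sparse.diags(inv_sqrt)
    return (d @ adjacency @ d).tocsr()


def _type_indicator(cell_types: pd.Series, categories: pd.Index) -> np.ndarray:
    codes = pd.Categorical(cell_types, categories=categories).codes
    if np.any(codes < 0):
        raise ValueError("cell type outside the shared category order")
    indicator = np.zeros((len(codes), len(categories)))
    indicator[np.arange(len(codes)), codes] = 1.0
    return indicator


def build_niche_graph(
    cells: pd.DataFrame,
    k: int = 50,
    sigma_rank: int = 20,
    categories: pd.Index | None = None,
    sample: str = "sample",
) -> NicheGraph:
    """Assemble the full niche graph for one sample's cell table."""
    coord_cols = ["x", "y", "z"] if "z" in cells.columns else ["x", "y"]
    coords = cells[coord_cols].to_numpy(dtype=float)
    if categories is None:
        categories = pd.Index(sorted(cells["Cell_Type"].unique()))
    # compute enough neighbors for both the niche size k and the sigma rank
    indices, distances = build_knn(coords, max(k, sigma_rank))
    kk = min(k, indices.shape[1])
    sigma0 = distances[:, min(sigma_rank, indices.shape[1]) - 1].copy()
    adjacency = build_niche_adjacency(indices[:, :kk])
    weights, sigma = cell_niche_weights(
        indices[:, :kk], distances[:, :kk], sigma=sigma0
    )
    composition = composition_vectors(weights, _type_indicator(cells["Cell_Type"], categories))
    return NicheGraph(
        sample=sample,
        cell_ids=cells["Cell_ID"].to_numpy(),
        adjacency=adjacency,
        weights=weights,
        composition=composition,
        sigma=sigma,
        cell_types=categories,
    )


def build_niche_graphs(
    cells: pd.DataFrame, k: int = 50, sigma_rank: int = 20
) -> list[NicheGraph]:
    """Build one niche graph per sample with a shared cell-type order."""
    categories = pd.Index(sorted(cells["Cell_Type"].unique()))
    if len(categories) < 2:
        raise ValueError("need at least two cell types")
    graphs = []
    for sample, group in cells.groupby("Sample", sort=True):
        graphs.append(
            build_niche_graph(
                group.reset_index(drop=True),
                k=k,
                sigma_rank=sigma_rank,
                categories=categories,
                sample=str(sample),
            )
        )
    return graphs
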