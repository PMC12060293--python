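"""Niche-cluster network, trajectory ordering and NT scores.

The soft cluster assignments pool the niche network into a K x K cluster
connectivity matrix E(k,l) = sum_ij c_ik a_ij c_jl (summed over samples),
normalized as E~(k,l) = E(k,l) / (rowsum_k * colsum_l).  The niche
trajectory is the Hamiltonian path over the K clusters maximizing the
summed normalized connectivity of consecutive pairs; the search is exact
(full enumeration for small K, Held-Karp dynamic programming up to
K = 18).  Cluster p_k on the path gets the score (k-1)/(K-1); niche and
cell scores are the assignment- and association-weighted averages, so
every emitted NT score lies in [0, 1].
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import sparse

__all__ = [
    "ClusterNetwork",
    "TrajectoryResult",
    "cluster_connectivity",
    "optimal_ordering",
    "niche_nt_scores",
    "cell_nt_scores",
    "orient_trajectory",
    "build_trajectory",
]

_ENUM_LIMIT = 10
_DP_LIMIT = 18


@dataclass
class ClusterNetwork:
    """Raw (E) and normalized (E_norm) connectivity between niche clusters."""

    E: np.ndarray
    E_norm: np.ndarray


@dataclass
class TrajectoryResult:
    """The 1-D niche trajectory and all derived scores."""

    ordering: np.ndarray  # permutation of cluster indices along the path
    cluster_scores: np.ndarray  # score of cluster k (indexed by cluster id)
    niche_scores: np.ndarray  # s_j per niche, concatenated over samples
    cell_scores: np.ndarray  # s~_i per cell, same order as niche_scores
    orientation: int = 1

    def flipped(self) -> "TrajectoryResult":
        return TrajectoryResult(
            ordering=self.ordering[::-1].copy(),
            cluster_scores=1.0 - self.cluster_scores,
            niche_scores=1.0 - self.niche_scores,
            cell_scores=1.0 - self.cell_scores,
            orientation=-self.orientation,
        )


def cluster_connectivity(assignments, adjacencies) -> ClusterNetwork:
    """Pool per-sample niche adjacencies into the cluster network.

    ``assignments`` and ``adjacencies`` are parallel per-sample lists; the
    raw connectivity E = sum_samples C^T A C is computed before
    normalization so all samples share a single trajectory.
    """
    if len(assignments) != len(adjacencies):
        raise ValueError("one assignment block per adjacency required")
    k = assignments[0].shape[1]
    e = np.zeros((k, k))
    for c, a in zip(assignments, adjacencies):
        e += c.T @ (sparse.csr_matrix(a) @ c)
    if not e.any():
        raise ValueError("degenerate clustering: all-zero cluster connectivity")
    row = e.sum(axis=1, keepdims=True)
    col = e.sum(axis=0, keepdims=True)
    denom = row * col
    e_norm = np.divide(e, denom, out=np.zeros_like(e), where=denom > 0.0)
    return ClusterNetwork(E=e, E_norm=e_norm)


def _path_weight(e_norm: np.ndarray, path) -> float:
    return float(sum(e_norm[path[i], path[i + 1]] for i in range(len(path) - 1)))


def _enumerate_ordering(e_norm: np.ndarray) -> np.ndarray:
    k = e_norm.shape[0]
    best, best_w = None, -np.inf
    for perm in itertools.permutations(range(k)):
        if perm[0] > perm[-1]:  # each undirected path once, lexicographic rep
            continue
        w = _path_weight(e_norm, perm)
        # permutations() yields lexicographically, so with a strict > the
        # first maximal path kept is the lexicographically smallest one
        if w > best_w:
            best, best_w = perm, w
    return np.array(best)


def _held_karp_ordering(e_norm: np.ndarray) -> np.ndarray:
    """Exact maximum-weight Hamiltonian path by subset dynamic programming."""
    k = e_norm.shape[0]
    full = 1 << k
    dp = np.full((full, k), -np.inf)
    parent = np.full((full, k), -1, dtype=int)
    for v in range(k):
        dp[1 << v, v] = 0.0
    for mask in range(full):
        for v in range(k):
            if dp[mask, v] == -np.inf:
                continue
            for u in range(k):
                if mask & (1 << u):
                    continue
                nm = mask | (1 << u)
                w = dp[mask, v] + e_norm[v, u]
                if w > dp[nm, u]:
                    dp[nm, u] = w
                    parent[nm, u] = v
    end = int(np.argmax(dp[full - 1]))
    path = [end]
    mask = full - 1
    while parent[mask, path[-1]] >= 0:
        prev = parent[mask, path[-1]]
        mask ^= 1 << path[-1]
        path.append(prev)
    path.reverse()
    if path[0] > path[-1]:
        path.reverse()
    return np.array(path)


def optimal_ordering(e_norm: np.ndarray) -> np.ndarray:
    """Exact maximum-connectivity Hamiltonian path over the cluster graph.

    Full enumeration (all K!/2 undirected paths) for K <= 10, Held-Karp
    dynamic programming for K <= 18; ties resolved to the lexicographically
    smallest representative with first endpoint < last endpoint.
    """
    e_norm = np.asarray(e_norm, dtype=float)
    k = e_norm.shape[0]
    if k < 2:
        raise ValueError("need at least two clusters to order")
    if k <= _ENUM_LIMIT:
        return _enumerate_ordering(e_norm)
    if k <= _DP_LIMIT:
        return _held_karp_ordering(e_norm)
    raise ValueError(f"exact ordering supported up to K={_DP_LIMIT}, got {k}")


def niche_nt_scores(assignment: np.ndarray, ordering: np.ndarray) -> np.ndarray:
    """Niche scores s_j = sum_k c_jk s(k) with s(p_k) = (k-1)/(K-1)."""
    k = len(ordering)
    cluster_scores = np.empty(k)
    if k == 1:
        warnings.warn("single cluster: all NT scores are 0", stacklevel=2)
        cluster_scores[:] = 0.0
    else:
        cluster_scores[np.asarray(ordering)] = np.arange(k) / (k - 1)
    return assignment @ cluster_scores


def cluster_score_vector(ordering: np.ndarray) -> np.ndarray:
    """Equally spaced cluster scores indexed by cluster id."""
    k = len(ordering)
    scores = np.empty(k)
    scores[np.asarray(ordering)] = np.arange(k) / max(k - 1, 1)
    return scores


def cell_nt_scores(weights: sparse.spmatrix, niche_scores: np.ndarray) -> np.ndarray:
    """Cell scores s~_i = sum_j w_ij s_j / sum_j w_ij (association-weighted)."""
    w = sparse.csr_matrix(weights)
    totals = np.asarray(w.sum(axis=1)).ravel()
    assert np.all(totals > 0.0), "every cell anchors a niche, so w-total > 0"
    return (w @ np.asarray(niche_scores)) / totals


def orient_trajectory(
    result: TrajectoryResult, reference: np.ndarray | None = None
) -> TrajectoryResult:
    """Fix the arbitrary trajectory direction against a per-cell reference.

    When the Spearman correlation of the cell scores with the reference is
    negative, all scores are mirrored (s -> 1 - s) and the orientation flag
    flipped; with no reference the result is returned unchanged.
    """
    if reference is None:
        return result
    from scipy.stats import spearmanr

    rho = spearmanr(result.cell_scores, np.asarray(reference)).statistic
    if np.isnan(rho):
        warnings.warn("constant scores; orientation left unchanged", stacklevel=2)
        return result
    return result.flipped() if rho < 0.0 else result


def build_trajectory(graphs, assignments, reference=None) -> tuple[ClusterNetwork, TrajectoryResult]:
    """Cluster network + ordering + niche/cell NT scores for trained assignments."""
    network = cluster_connectivity(assignments, [g.adjacency for g in graphs])
    ordering = optimal_ordering(network.E_norm)
    cscores = cluster_score_vector(ordering)
    niche_scores = np.concatenate([c @ cscores for c in assignments])
    cell_scores = np.concatenate(
        [
            cell_nt_scores(g.weights, c @ cscores)
            for g, c in zip(graphs, assignments)
        ]
    )
    result = TrajectoryResult(
        ordering=ordering,
        cluster_scores=cscores,
        niche_scores=niche_scores,
        cell_scores=cell_scores,
    )
    return network, orient_trajectory(result, reference)
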