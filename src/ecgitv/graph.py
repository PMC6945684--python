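"""Trajectory-similarity graph and the weighted graph-TV norm.

The key idea of graph-based TV reconstruction: instead of penalising
differences only between spatially adjacent heart nodes, build a KNN graph
whose notion of adjacency is similarity of the nodes' TMP *time courses*.
Two nodes whose trajectories u_i(t), u_j(t) are close in Euclidean distance
are likely in the same electrophysiological state (both scar, or activated
at nearly the same time) even when far apart in space, and the TV penalty
between them is weighted up accordingly.

The graph is built once from a low-resolution initial estimate (typically
the Tikhonov solution) and exposes a sparse weighted gradient operator D
with one row per edge carrying +sqrt(W_ij) at node i and -sqrt(W_ij) at
node j, so that the graph-TV norm is the entrywise L1 norm of D @ U.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import scipy.sparse as sp
from scipy.spatial.distance import cdist

__all__ = [
    "TrajectoryGraph",
    "trajectory_distance",
    "knn_graph",
    "compute_weights",
    "build_trajectory_graph",
    "graph_tv_norm",
]


@dataclass
class TrajectoryGraph:
    """Weighted KNN graph over heart nodes.

    Attributes
    ----------
    k : neighbour count used in the KNN search (0 for hand-built graphs)
    edges : (E, 2) int array of unique undirected edges, each row (i, j), i<j
    n_nodes : number of graph nodes n
    distances : (E,) trajectory distance per edge (may be None before
        :func:`compute_weights`)
    weights : (E,) Gaussian similarity weights in (0, 1], or None
    sigma_bandwidth : Gaussian bandwidth (mV) — the mean trajectory distance
        over retained edges — or None
    grad_operator : (E, n) sparse weighted gradient operator D, or None
    """

    k: int
    edges: np.ndarray
    n_nodes: int
    distances: Optional[np.ndarray] = None
    weights: Optional[np.ndarray] = None
    sigma_bandwidth: Optional[float] = None
    grad_operator: Optional[sp.spmatrix] = None

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def neighbor_sets(self) -> list[np.ndarray]:
        """Post-symmetrisation neighbour list n_i for each node."""
        nbrs: list[list[int]] = [[] for _ in range(self.n_nodes)]
        for i, j in self.edges:
            nbrs[int(i)].append(int(j))
            nbrs[int(j)].append(int(i))
        return [np.array(sorted(s), dtype=np.intp) for s in nbrs]

    @classmethod
    def from_edges(
        cls,
        n_nodes: int,
        edges: Sequence,
        weights: Optional[np.ndarray] = None,
    ) -> "TrajectoryGraph":
        """Build a graph directly from an edge list (e.g. spatial adjacency)
        with given weights (default: all ones)."""
        edges = np.asarray(
            [(min(i, j), max(i, j)) for i, j in np.asarray(edges, dtype=np.intp)],
            dtype=np.intp,
        )
        edges = np.unique(edges, axis=0)
        if weights is None:
            weights = np.ones(edges.shape[0])
        g = cls(k=0, edges=edges, n_nodes=n_nodes, weights=np.asarray(weights, float))
        g.grad_operator = _assemble_grad(edges, g.weights, n_nodes)
        return g


def trajectory_distance(u_i: np.ndarray, u_j: np.ndarray) -> float:
    """Euclidean distance between two nodes' TMP time courses."""
    u_i = np.asarray(u_i, dtype=float)
    u_j = np.asarray(u_j, dtype=float)
    if u_i.shape != u_j.shape:
        raise ValueError(f"trajectory length mismatch: {u_i.shape} vs {u_j.shape}")
    return float(np.linalg.norm(u_i - u_j))


def knn_graph(U_init: np.ndarray, k: int) -> TrajectoryGraph:
    """KNN search on trajectory distance; returns the edge skeleton.

    For each node the ``k`` nearest other nodes (smallest trajectory
    distance, ties broken toward the lower index) are taken as directed
    neighbours; the directed lists are symmetrised by union into undirected
    edges, so every node keeps at least ``k`` neighbours.
    """
    U_init = np.atleast_2d(np.asarray(U_init, dtype=float))
    n = U_init.shape[0]
    if not 1 <= k < n:
        raise ValueError(f"k must satisfy 1 <= k < n={n}, got {k}")
    d = cdist(U_init, U_init, "sqeuclidean")
    np.fill_diagonal(d, np.inf)
    order = np.argsort(d, axis=1, kind="stable")[:, :k]
    pairs = {
        (min(i, int(j)), max(i, int(j))) for i in range(n) for j in order[i]
    }
    edges = np.array(sorted(pairs), dtype=np.intp)
    return TrajectoryGraph(k=k, edges=edges, n_nodes=n)


def _assemble_grad(
    edges: np.ndarray, weights: np.ndarray, n: int
) -> sp.csr_matrix:
    """Sparse E x n operator with rows (+sqrt(w), -sqrt(w)) per edge."""
    e = edges.shape[0]
    sw = np.sqrt(weights)
    rows = np.repeat(np.arange(e), 2)
    cols = edges.ravel()
    data = np.column_stack([sw, -sw]).ravel()
    return sp.csr_matrix((data, (rows, cols)), shape=(e, n))


def compute_weights(U_init: np.ndarray, graph: TrajectoryGraph) -> TrajectoryGraph:
    """Attach Gaussian similarity weights and the gradient operator.

    The bandwidth ``sigma`` is the mean trajectory distance over the
    retained (post-KNN) edges; each edge gets ``W_ij = exp(-l_ij^2/sigma^2)``.
    If every retained pair of trajectories is identical (sigma = 0) all
    weights fall back to 1, the similarity-graph analogue of an unweighted
    graph.
    """
    U_init = np.atleast_2d(np.asarray(U_init, dtype=float))
    if graph.n_edges == 0:
        raise ValueError("graph has no edges")
    diffs = U_init[graph.edges[:, 0]] - U_init[graph.edges[:, 1]]
    ell = np.linalg.norm(diffs, axis=1)
    sigma = float(ell.mean())
    if sigma == 0.0:
        weights = np.ones_like(ell)
    else:
        weights = np.exp(-(ell**2) / sigma**2)
    return TrajectoryGraph(
        k=graph.k,
        edges=graph.edges,
        n_nodes=graph.n_nodes,
        distances=ell,
        weights=weights,
        sigma_bandwidth=sigma,
        grad_operator=_assemble_grad(graph.edges, weights, graph.n_nodes),
    )


def build_trajectory_graph(U_init: np.ndarray, k: int = 5) -> TrajectoryGraph:
    """KNN search + Gaussian weighting in one call (the usual entry point)."""
    return compute_weights(U_init, knn_graph(U_init, k))


def graph_tv_norm(U: np.ndarray, graph: TrajectoryGraph) -> float:
    """Weighted graph total variation: sum over edges and frames of
    sqrt(W_ij) |U[i, s] - U[j, s]|, i.e. the entrywise L1 norm of D @ U."""
    U = np.atleast_2d(np.asarray(U, dtype=float))
    if graph.grad_operator is None:
        raise ValueError("graph has no weights; call compute_weights first")
    if U.shape[0] != graph.n_nodes:
        raise ValueError(
            f"U has {U.shape[0]} rows but graph has {graph.n_nodes} nodes"
        )
    return float(np.abs(graph.grad_operator @ U).sum())
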