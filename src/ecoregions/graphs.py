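"""Spatial constraint and feature-similarity matrices and their combination.

The spatial constraint matrix Q is binary: Q_ij = 1 iff units i and j are
within δ hops of each other on the contiguity graph (Q_ii = 1).  Feature
similarity W is a Gaussian radial basis kernel on Euclidean distance in the
embedding, W_ij = exp(-d_ij^2 / (2 σ^2)).  The combined affinity is the
Hadamard (elementwise) product S = W ∘ Q: the constraint masks the
similarity so only pairs within the δ-neighborhood retain affinity, which
is why small δ yields strongly contiguous regions and large δ relaxes the
spatial structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.spatial.distance import pdist, squareform

from .io import AdjacencyGraph
from .preprocess import FeatureEmbedding

#: refuse dense materialization above this many units (override explicitly)
DENSE_LIMIT = 30_000


@dataclass
class ConstraintMatrix:
    """Binary δ-neighborhood matrix Q (sparse, symmetric, unit diagonal)."""

    delta: int
    Q: sparse.csr_matrix
    unit_ids: list[str]

    @property
    def n(self) -> int:
        return self.Q.shape[0]


@dataclass
class SimilarityMatrix:
    """Gaussian feature similarity W with bandwidth σ; ``combined`` = W ∘ Q."""

    W: np.ndarray
    bandwidth: float
    unit_ids: list[str]
    combined: sparse.csr_matrix | None = None

    @property
    def n(self) -> int:
        return self.W.shape[0]


def hop_distance_within(A: sparse.csr_matrix, delta: int) -> sparse.csr_matrix:
    """Boolean reach matrix: (i, j) nonzero iff BFS hop distance <= delta."""
    n = A.shape[0]
    reach = ((sparse.identity(n, format="csr") + A) > 0).astype(bool)
    step = reach.copy()
    for _ in range(delta - 1):
        nxt = ((step @ reach) > 0).astype(bool)
        if nxt.nnz == step.nnz:
            break  # closure reached before delta hops
        step = nxt
    return step.astype(np.int8).tocsr()


def build_constraint_matrix(graph: AdjacencyGraph, delta: int,
                            order: list[str] | None = None) -> ConstraintMatrix:
    """Q_ij = 1 iff hop-distance(i, j) <= delta on the contiguity graph."""
    if delta < 1:
        raise ValueError(f"delta must be >= 1, got {delta}")
    if graph.n_units == 0:
        raise ValueError("empty graph")
    order = order if order is not None else list(graph.unit_ids)
    A = graph.to_sparse(order=order)
    Q = hop_distance_within(A, delta)
    return ConstraintMatrix(delta=delta, Q=Q, unit_ids=order)


def default_bandwidth(embedding: FeatureEmbedding, graph: AdjacencyGraph) -> float:
    """Median embedding distance over adjacent (δ=1) unit pairs.

    Scale-adaptive and resolution-independent: halving all distances halves
    σ, leaving W unchanged.  Falls back to the median over all pairs when
    the graph has no edges or all adjacent pairs coincide.
    """
    idx = {u: i for i, u in enumerate(embedding.unit_id)}
    d = []
    for e in graph.edges:
        a, b = tuple(e)
        if a in idx and b in idx:
            d.append(float(np.linalg.norm(embedding.scores[idx[a]] - embedding.scores[idx[b]])))
    d = [x for x in d if x > 0]
    if d:
        return float(np.median(d))
    allpair = pdist(embedding.scores)
    allpair = allpair[allpair > 0]
    if allpair.size == 0:
        return 1.0  # all points identical; any σ gives W = all-ones
    return float(np.median(allpair))


def build_feature_similarity(embedding: FeatureEmbedding,
                             bandwidth: float | None = None,
                             graph: AdjacencyGraph | None = None) -> SimilarityMatrix:
    """Gaussian RBF similarity W_ij = exp(-d_ij^2 / (2 σ^2)) on the embedding.

    If ``bandwidth`` is None, σ defaults to the median adjacent-pair distance
    (requires ``graph``).
    """
    n = embedding.scores.shape[0]
    if n < 2:
        raise ValueError("need at least 2 units")
    if n > DENSE_LIMIT:
        raise ValueError(
            f"refusing to build a dense {n} x {n} similarity matrix "
            f"(limit {DENSE_LIMIT}); increase graphs.DENSE_LIMIT explicitly"
        )
    if bandwidth is None:
        if graph is None:
            raise ValueError("provide a bandwidth or a graph for the default heuristic")
        bandwidth = default_bandwidth(embedding, graph)
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    d2 = squareform(pdist(embedding.scores, metric="sqeuclidean"))
    W = np.exp(-d2 / (2.0 * bandwidth**2))
    return SimilarityMatrix(W=W, bandwidth=float(bandwidth), unit_ids=list(embedding.unit_id))


def combine_similarity(sim: SimilarityMatrix, constraint: ConstraintMatrix) -> SimilarityMatrix:
    """Hadamard product S = W ∘ Q; S inherits Q's sparsity pattern."""
    if sim.n != constraint.n:
        raise ValueError(f"dimension mismatch: W is {sim.n}, Q is {constraint.n}")
    if sim.unit_ids != constraint.unit_ids:
        raise ValueError("unit order mismatch between similarity and constraint")
    Q = constraint.Q.tocoo()
    data = sim.W[Q.row, Q.col] * Q.data
    S = sparse.csr_matrix((data, (Q.row, Q.col)), shape=Q.shape)
    return SimilarityMatrix(
        W=sim.W, bandwidth=sim.bandwidth, unit_ids=sim.unit_ids, combined=S
    )
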