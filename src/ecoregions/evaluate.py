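"""Quality metrics for a regionalization: homogeneity and contiguity.

Landscape homogeneity is scored by the within- and between-region sums of
squares (SSW, SSB) of the feature space, which partition the total sum of
squares exactly.  Spatial contiguity is scored by PctML — the percentage of
must-link pairs (units within ``eval_delta`` hops of each other) assigned
to the same region — and by the count of regions whose induced δ=1
subgraph is connected.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.csgraph import connected_components

from .cluster import Regionalization
from .graphs import build_constraint_matrix
from .io import AdjacencyGraph


@dataclass
class ClusterQualityReport:
    ssw: float
    ssb: float
    total_ss: float
    ratio: float          # SSW : SSB (inf when SSB = 0)
    pct_ml: float         # percent of must-link pairs preserved, in [0, 100]
    eval_delta: int
    n_contiguous: int     # regions whose induced adjacency subgraph is connected
    k: int

    def to_dict(self) -> dict:
        return {
            "ssw": self.ssw, "ssb": self.ssb, "total_ss": self.total_ss,
            "ratio": self.ratio, "pct_ml": self.pct_ml,
            "eval_delta": self.eval_delta, "n_contiguous": self.n_contiguous,
            "k": self.k,
        }


def within_between_ss(points: np.ndarray, labels: np.ndarray) -> tuple[float, float, float]:
    """One-way decomposition: (SSW, SSB, total SS) of points about region means.

    SSW = Σ_regions Σ_{i in region} ||x_i - x̄_region||²,
    SSB = Σ_regions n_region ||x̄_region - x̄||², and SSW + SSB = total SS.
    """
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.shape[0] == 1:
        points = points.T
    grand = points.mean(axis=0)
    total = float(((points - grand) ** 2).sum())
    ssw = 0.0
    ssb = 0.0
    for c in np.unique(labels):
        block = points[labels == c]
        mu = block.mean(axis=0)
        ssw += float(((block - mu) ** 2).sum())
        ssb += block.shape[0] * float(((mu - grand) ** 2).sum())
    return ssw, ssb, total


def pct_must_link(regionalization: Regionalization, graph: AdjacencyGraph,
                  eval_delta: int) -> float:
    """Percent of unordered unit pairs within eval_delta hops sharing a label."""
    order = list(regionalization.unit_id)
    Q = build_constraint_matrix(graph, eval_delta, order=order).Q
    Qu = sparse.triu(Q, k=1).tocoo()
    if Qu.nnz == 0:
        return 100.0
    labels = regionalization.label
    same = labels[Qu.row] == labels[Qu.col]
    return 100.0 * float(same.sum()) / Qu.nnz


def count_contiguous_regions(regionalization: Regionalization,
                             graph: AdjacencyGraph) -> int:
    """Number of regions whose induced adjacency subgraph is connected."""
    order = list(regionalization.unit_id)
    A = graph.to_sparse(order=order)
    labels = regionalization.label
    count = 0
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        sub = A[np.ix_(idx, idx)]
        n_comp, _ = connected_components(sub, directed=False)
        if n_comp == 1:
            count += 1
    return count


def evaluate_regionalization(regionalization: Regionalization, space: np.ndarray,
                             graph: AdjacencyGraph, eval_delta: int = 1) -> ClusterQualityReport:
    """Score a regionalization for homogeneity (SSW/SSB) and contiguity (PctML).

    ``space`` is the feature matrix (rows aligned with the regionalization's
    units) in which the sums of squares are computed — typically the
    standardized variables, or the PCA scores, or a single response column.
    """
    space = np.atleast_2d(np.asarray(space, dtype=float))
    if space.shape[0] == 1:
        space = space.T
    n = regionalization.n_units
    if space.shape[0] != n:
        raise ValueError(
            f"space has {space.shape[0]} rows but regionalization has {n} units")
    if n < 2:
        raise ValueError("need at least 2 units")
    if eval_delta < 1:
        raise ValueError("eval_delta must be >= 1")

    ssw, ssb, total = within_between_ss(space, regionalization.label)
    ratio = ssw / ssb if ssb > 0 else float("inf")
    return ClusterQualityReport(
        ssw=ssw, ssb=ssb, total_ss=total, ratio=ratio,
        pct_ml=pct_must_link(regionalization, graph, eval_delta),
        eval_delta=eval_delta,
        n_contiguous=count_contiguous_regions(regionalization, graph),
        k=regionalization.k,
    )
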