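"""Regionalization by spatially constrained spectral clustering and baselines.

Four methods produce a unit -> region assignment:

* ``SSC``  — spatially constrained spectral clustering: spectral embedding of
  the combined affinity S = W ∘ Q (Gaussian feature similarity masked by the
  δ-hop constraint), then restarted k-means on the eigenvectors.
* ``SC``   — contiguity-only spectral clustering: same pipeline on Q alone
  (equivalently, constant feature similarity), ignoring landscape homogeneity.
* ``KMEANS`` — k-means directly on the feature embedding, ignoring space.
* ``RANDOM`` — uniform random labels with no empty region, the null used for
  choosing the number of regions.

The spectral step solves the generalized eigenproblem L u = λ D u with
L = D - S and D = diag(row sums), i.e. random-walk normalized spectral
clustering, and k-means keeps the restart with the lowest within-cluster
sum of squares.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy import sparse
from scipy.linalg import eigh
from scipy.sparse.csgraph import connected_components
from sklearn.cluster import KMeans

from .graphs import SimilarityMatrix, build_constraint_matrix, build_feature_similarity, combine_similarity
from .io import AdjacencyGraph
from .preprocess import FeatureEmbedding

Method = Literal["SSC", "SC", "KMEANS", "RANDOM"]

#: above this size the spectral step switches from a dense generalized
#: eigensolver to sparse shift-invert Lanczos
_DENSE_EIG_LIMIT = 2000


@dataclass
class ClusterConfig:
    k: int
    method: Method = "SSC"
    delta: int | None = None
    restarts: int = 1000
    seed: int = 0
    bandwidth: float | None = None
    restart_selection_space: Literal["embedding", "features"] = "embedding"
    row_normalize: bool = False

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.restarts < 1:
            raise ValueError("restarts must be >= 1")
        needs_delta = self.method in ("SSC", "SC")
        if needs_delta and (self.delta is None or self.delta < 1):
            raise ValueError(f"method {self.method} requires a positive delta")
        if not needs_delta and self.delta is not None:
            raise ValueError(f"method {self.method} takes no delta")


@dataclass
class Regionalization:
    """A unit -> region assignment with full provenance.

    Labels are integers 1..k; label identity is arbitrary (every downstream
    metric is invariant to permuting them).
    """

    unit_id: list[str]
    label: np.ndarray
    k: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.label = np.asarray(self.label, dtype=int)
        if len(self.unit_id) != self.label.shape[0]:
            raise ValueError("unit_id / label length mismatch")
        if self.label.min() < 1 or self.label.max() > self.k:
            raise ValueError(f"labels must lie in 1..{self.k}")
        present = np.unique(self.label)
        if present.size != self.k:
            missing = sorted(set(range(1, self.k + 1)) - set(present.tolist()))
            raise ValueError(f"empty region label(s): {missing}")

    @property
    def n_units(self) -> int:
        return len(self.unit_id)

    def labels_for(self, unit_ids: list[str]) -> np.ndarray:
        lookup = dict(zip(self.unit_id, self.label))
        return np.array([lookup[u] for u in unit_ids], dtype=int)


def spectral_embed(S: sparse.spmatrix | np.ndarray, k: int,
                   row_normalize: bool = False,
                   allow_disconnected: bool = False) -> np.ndarray:
    """Eigenvectors of L u = λ D u for the k smallest eigenvalues.

    L = D - S is the unnormalized graph Laplacian of the affinity S and D
    its degree matrix; the generalized problem is the random-walk normalized
    spectral embedding.  Columns come in ascending eigenvalue order with a
    deterministic sign convention (largest-magnitude entry positive).
    ``row_normalize`` additionally projects embedding rows to the unit
    sphere (the Ng–Jordan–Weiss variant).

    A disconnected affinity graph is an error by default (spatially
    isolated units must be removed or bridged before clustering);
    ``allow_disconnected`` permits the eigenanalysis anyway, in which case
    eigenvalue 0 has multiplicity equal to the number of components and
    the corresponding eigenvectors are constant within components.
    """
    S = sparse.csr_matrix(S)
    n = S.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    n_comp, _ = connected_components(S, directed=False)
    if n_comp > 1 and not allow_disconnected:
        raise ValueError(
            f"affinity graph has {n_comp} connected components; remove spatially "
            "isolated units (islands) or bridge them before clustering"
        )
    d = np.asarray(S.sum(axis=1)).ravel()
    if np.any(d <= 0):
        raise ValueError("zero row-sum in the affinity matrix")

    if n <= _DENSE_EIG_LIMIT:
        L = np.diag(d) - S.toarray()
        vals, vecs = eigh(L, np.diag(d), subset_by_index=[0, k - 1])
    else:
        L = sparse.diags(d) - S
        D = sparse.diags(d)
        vals, vecs = sparse.linalg.eigsh(L.tocsc(), k=k, M=D.tocsc(),
                                         sigma=-1e-5, which="LM")
        order = np.argsort(vals)
        vals, vecs = vals[order], vecs[:, order]

    # deterministic sign: flip so each vector's largest-|.| entry is positive
    for j in range(vecs.shape[1]):
        i = int(np.argmax(np.abs(vecs[:, j])))
        if vecs[i, j] < 0:
            vecs[:, j] = -vecs[:, j]
    if row_normalize:
        norms = np.linalg.norm(vecs, axis=1, keepdims=True)
        norms[norms < 1e-15] = 1.0
        vecs = vecs / norms
    return vecs


def _ssw_of(points: np.ndarray, labels: np.ndarray) -> float:
    total = 0.0
    for c in np.unique(labels):
        block = points[labels == c]
        total += float(((block - block.mean(axis=0)) ** 2).sum())
    return total


def kmeans_min_ssw(points: np.ndarray, k: int, restarts: int, seed: int,
                   selection_points: np.ndarray | None = None) -> tuple[np.ndarray, float]:
    """Restarted k-means; returns (labels in 0..k-1, best objective).

    Each restart is seeded k-means++ from an independent stream spawned off
    ``seed``; the winner has the lowest within-cluster sum of squares,
    computed in ``selection_points`` when given (else the clustered space).
    The best-so-far objective is non-increasing in the number of restarts
    under a fixed seed, so results are reproducible and prefix-consistent.
    """
    points = np.asarray(points, dtype=float)
    n = points.shape[0]
    if k > n:
        raise ValueError(f"k={k} exceeds n={n}")
    streams = np.random.SeedSequence(seed).spawn(restarts)
    best_labels: np.ndarray | None = None
    best_obj = np.inf
    for child in streams:
        rs = int(child.generate_state(1)[0] % (2**31 - 1))
        km = KMeans(n_clusters=k, n_init=1, random_state=rs).fit(points)
        obj = float(km.inertia_) if selection_points is None else _ssw_of(
            selection_points, km.labels_)
        if obj < best_obj - 1e-12:
            best_obj, best_labels = obj, km.labels_.copy()
    assert best_labels is not None
    return best_labels, best_obj


def _random_labels(n: int, k: int, rng: np.random.Generator,
                   max_tries: int = 1000) -> np.ndarray:
    """Uniform labels in 0..k-1, resampled until no label is empty."""
    for _ in range(max_tries):
        lab = rng.integers(0, k, size=n)
        if np.unique(lab).size == k:
            return lab
    # n barely above k: fall back to a permutation-based fill
    lab = np.concatenate([np.arange(k), rng.integers(0, k, size=n - k)])
    return rng.permutation(lab)


def cluster_regions(embedding: FeatureEmbedding | None, graph: AdjacencyGraph | None,
                    config: ClusterConfig,
                    n_units: int | None = None,
                    unit_ids: list[str] | None = None) -> Regionalization:
    """Produce a regionalization by the configured method.

    SSC needs embedding + graph + δ; SC needs graph + δ (feature similarity
    replaced by the constraint alone); KMEANS needs only the embedding;
    RANDOM needs only n, k and the seed.
    """
    prov: dict = {
        "method": config.method, "k": config.k, "delta": config.delta,
        "restarts": config.restarts, "seed": config.seed,
    }

    if config.method == "RANDOM":
        if unit_ids is None:
            if embedding is not None:
                unit_ids = list(embedding.unit_id)
            elif graph is not None:
                unit_ids = list(graph.unit_ids)
            elif n_units is not None:
                unit_ids = [f"u{i}" for i in range(n_units)]
            else:
                raise ValueError("RANDOM needs unit ids or n_units")
        rng = np.random.default_rng(config.seed)
        labels0 = _random_labels(len(unit_ids), config.k, rng)
        return Regionalization(unit_id=unit_ids, label=labels0 + 1, k=config.k,
                               provenance=prov)

    if config.method == "KMEANS":
        if embedding is None:
            raise ValueError("KMEANS requires a feature embedding")
        labels0, obj = kmeans_min_ssw(embedding.scores, config.k, config.restarts,
                                      config.seed)
        prov["objective"] = obj
        return Regionalization(unit_id=list(embedding.unit_id),
                               label=_relabel(labels0) + 1, k=config.k, provenance=prov)

    # spectral methods
    if graph is None:
        raise ValueError(f"{config.method} requires a contiguity graph")
    if config.method == "SSC" and embedding is None:
        raise ValueError("SSC requires a feature embedding")

    order = list(embedding.unit_id) if embedding is not None else list(graph.unit_ids)
    constraint = build_constraint_matrix(graph, config.delta, order=order)
    if config.method == "SSC":
        sim = build_feature_similarity(embedding, bandwidth=config.bandwidth, graph=graph)
        sim = combine_similarity(sim, constraint)
        S = sim.combined
        prov["bandwidth"] = sim.bandwidth
    else:  # SC: affinity is the binary constraint itself
        S = constraint.Q.astype(float)

    coords = spectral_embed(S, config.k, row_normalize=config.row_normalize)
    selection = None
    if config.restart_selection_space == "features" and embedding is not None:
        selection = embedding.scores
    labels0, obj = kmeans_min_ssw(coords, config.k, config.restarts, config.seed,
                                  selection_points=selection)
    prov["objective"] = obj
    return Regionalization(unit_id=order, label=_relabel(labels0) + 1, k=config.k,
                           provenance=prov)


def _relabel(labels: np.ndarray) -> np.ndarray:
    """Map labels to 0..k-1 in order of first appearance (stable canonical form)."""
    _, first = np.unique(labels, return_index=True)
    order = labels[np.sort(first)]
    remap = {int(old): new for new, old in enumerate(order)}
    return np.array([remap[int(x)] for x in labels], dtype=int)
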