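"""Synthetic landscapes and point responses for testing every other module.

A rook-adjacency lattice stands in for real watershed polygons: it keeps
the planar contiguity structure the constraint machinery exercises while
making adjacency trivially verifiable.  Planted regions are contiguous by
construction — either seeded contiguous growth (irregular, watershed-like
shapes) or rectangular blocks (deterministic geometry for exact tests).
Features come in three theme blocks (terrestrial / climate / freshwater);
a random subset of each block is informative, carrying region-specific
means separated by ``effect_size`` within-region standard deviations, plus
Gaussian noise that can be spatially autocorrelated.  Missing cells and
inflated outliers are injected at the stated rates.  Point responses are a
region effect plus residual noise, with the region-effect variance solved
analytically so the expected among-region share of the sum of squares
equals a target fraction (e.g. 0.4).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
import pandas as pd
from scipy import ndimage

from .cluster import Regionalization
from .io import AdjacencyGraph, ResponseTable, SpatialUnitTable


@dataclass
class SyntheticLandscapeSpec:
    rows: int = 20
    cols: int = 20
    k_true: int = 4
    n_features: int = 10
    theme_split: tuple[int, int, int] | None = None  # default: near-even split
    effect_size: float = 3.0
    noise_sd: float = 1.0
    spatial_noise_range: float = 0.0
    missing_rate: float = 0.0
    outlier_rate: float = 0.0
    region_shape: Literal["growth", "blocks"] = "growth"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rows < 1 or self.cols < 1:
            raise ValueError("lattice dimensions must be positive")
        if not 1 <= self.k_true <= self.rows * self.cols:
            raise ValueError("k_true must be in 1..rows*cols")
        if self.theme_split is None:
            base = self.n_features // 3
            rem = self.n_features - 3 * base
            self.theme_split = (base + (rem > 0), base + (rem > 1), base)
        if sum(self.theme_split) != self.n_features:
            raise ValueError(
                f"theme_split {self.theme_split} does not sum to n_features={self.n_features}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must be in [0, 1)")
        if not 0 <= self.outlier_rate < 1:
            raise ValueError("outlier_rate must be in [0, 1)")
        if self.effect_size < 0:
            raise ValueError("effect_size must be non-negative")


@dataclass
class SyntheticResponseSpec:
    n_points: int = 2000
    among_fraction_true: float = 0.4
    residual_sd: float = 1.0
    points_per_unit: Literal["uniform", "proportional"] = "uniform"
    response_name: str = "response"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if not 0 <= self.among_fraction_true < 1:
            raise ValueError("among_fraction_true must be in [0, 1)")
        if self.residual_sd <= 0:
            raise ValueError("residual_sd must be positive")


def lattice_graph(rows: int, cols: int) -> AdjacencyGraph:
    """Rook-adjacency lattice; unit ids are "r{i}c{j}" in row-major order."""
    ids = [f"r{i}c{j}" for i in range(rows) for j in range(cols)]
    g = AdjacencyGraph(unit_ids=ids)
    for i in range(rows):
        for j in range(cols):
            if j + 1 < cols:
                g.add_edge(f"r{i}c{j}", f"r{i}c{j+1}")
            if i + 1 < rows:
                g.add_edge(f"r{i}c{j}", f"r{i+1}c{j}")
    return g


def _grow_regions(rows: int, cols: int, k: int, rng: np.random.Generator) -> np.ndarray:
    """Multi-source randomized BFS growth: contiguous, irregular regions."""
    n = rows * cols
    labels = np.full(n, -1, dtype=int)
    seeds = rng.choice(n, size=k, replace=False)
    frontier: list[list[int]] = [[int(s)] for s in seeds]
    for r, s in enumerate(seeds):
        labels[s] = r
    remaining = n - k
    while remaining > 0:
        order = rng.permutation(k)
        grew = False
        for r in order:
            new_frontier = []
            claimed = None
            for cell in frontier[r]:
                i, j = divmod(cell, cols)
                nbrs = []
                if i > 0:
                    nbrs.append(cell - cols)
                if i + 1 < rows:
                    nbrs.append(cell + cols)
                if j > 0:
                    nbrs.append(cell - 1)
                if j + 1 < cols:
                    nbrs.append(cell + 1)
                free = [x for x in nbrs if labels[x] == -1]
                if free:
                    claimed = int(rng.choice(free))
                    break
            if claimed is not None:
                labels[claimed] = r
                frontier[r] = [claimed] + frontier[r]
                remaining -= 1
                grew = True
            else:
                frontier[r] = []
        if not grew and remaining > 0:  # pragma: no cover - safety net
            labels[labels == -1] = 0
            remaining = 0
    return labels


def _block_regions(rows: int, cols: int, k: int) -> np.ndarray:
    """Deterministic rectangular blocks (quadrant-style planted regions)."""
    br = int(np.floor(np.sqrt(k)))
    while k % br:
        br -= 1
    bc = k // br
    row_edges = np.linspace(0, rows, br + 1).astype(int)
    col_edges = np.linspace(0, cols, bc + 1).astype(int)
    labels = np.empty(rows * cols, dtype=int)
    for i in range(rows):
        for j in range(cols):
            bi = int(np.searchsorted(row_edges, i, side="right") - 1)
            bj = int(np.searchsorted(col_edges, j, side="right") - 1)
            labels[i * cols + j] = min(bi, br - 1) * bc + min(bj, bc - 1)
    return labels


def _region_means(k: int, n_informative: int, separation: float,
                  rng: np.random.Generator) -> np.ndarray:
    """k x n_informative mean matrix with pairwise distance ≈ separation.

    With enough informative dimensions a regular simplex gives exactly equal
    pairwise separation; otherwise random directions are scaled so the
    root-mean-square pairwise distance matches.
    """
    if k == 1:
        return np.zeros((1, n_informative))
    if n_informative >= k:
        # centered identity: rows of I_k - 1/k have pairwise distance sqrt(2)
        out = np.zeros((k, n_informative))
        out[:, :k] = (np.eye(k) - 1.0 / k) * (separation / np.sqrt(2.0))
        return out
    M = rng.standard_normal((k, max(n_informative, 1)))
    diffs = M[:, None, :] - M[None, :, :]
    rms = np.sqrt((diffs**2).sum(-1)[np.triu_indices(k, 1)].mean()) if k > 1 else 1.0
    return M * (separation / rms if rms > 0 else 1.0)


def _spatial_noise(rows: int, cols: int, n_features: int, sd: float,
                   length_scale: float, rng: np.random.Generator) -> np.ndarray:
    if length_scale <= 0:
        return rng.normal(0.0, sd, size=(rows * cols, n_features))
    out = np.empty((rows * cols, n_features))
    for f in range(n_features):
        field = rng.standard_normal((rows, cols))
        field = ndimage.gaussian_filter(field, sigma=length_scale, mode="nearest")
        s = field.std()
        field = field / s * sd if s > 0 else field
        out[:, f] = field.ravel()
    return out


def generate_landscape(spec: SyntheticLandscapeSpec
                       ) -> tuple[SpatialUnitTable, AdjacencyGraph, np.ndarray]:
    """Generate (unit table, rook adjacency, true labels in 1..k_true).

    Every planted region's induced rook subgraph is connected by
    construction.  Fully reproducible: identical spec -> identical output.
    """
    rng = np.random.default_rng(spec.seed)
    graph = lattice_graph(spec.rows, spec.cols)
    n = spec.rows * spec.cols

    if spec.region_shape == "blocks":
        truth0 = _block_regions(spec.rows, spec.cols, spec.k_true)
    else:
        truth0 = _grow_regions(spec.rows, spec.cols, spec.k_true, rng)

    themes = ["terrestrial", "climate", "freshwater"]
    X = np.empty((n, spec.n_features))
    noise = _spatial_noise(spec.rows, spec.cols, spec.n_features, spec.noise_sd,
                           spec.spatial_noise_range, rng)
    names: list[str] = []
    theme_map: dict[str, str] = {}
    col = 0
    separation = spec.effect_size * spec.noise_sd
    for theme, size in zip(themes, spec.theme_split):
        if size == 0:
            continue
        n_inf = max(1, size // 2) if spec.effect_size > 0 else 0
        inf_cols = rng.choice(size, size=n_inf, replace=False) if n_inf else np.array([], int)
        means = np.zeros((spec.k_true, size))
        if n_inf:
            means[:, inf_cols] = _region_means(spec.k_true, n_inf, separation, rng)
        X[:, col:col + size] = means[truth0] + noise[:, col:col + size]
        for j in range(size):
            name = f"{theme[:4]}_{j}"
            names.append(name)
            theme_map[name] = theme
        col += size

    if spec.outlier_rate > 0:
        mask = rng.random(X.shape) < spec.outlier_rate
        X[mask] += np.sign(rng.standard_normal(int(mask.sum()))) * 10 * spec.noise_sd
    if spec.missing_rate > 0:
        mask = rng.random(X.shape) < spec.missing_rate
        X[mask] = np.nan

    table = SpatialUnitTable(unit_id=list(graph.unit_ids), values=X,
                             variable_names=names, themes=theme_map)
    return table, graph, truth0 + 1


def truth_regionalization(graph: AdjacencyGraph, truth: np.ndarray) -> Regionalization:
    """Wrap planted true labels (1..k) as a Regionalization."""
    return Regionalization(unit_id=list(graph.unit_ids),
                           label=np.asarray(truth, dtype=int),
                           k=int(np.max(truth)),
                           provenance={"method": "TRUTH"})


def generate_responses(spec: SyntheticResponseSpec,
                       regionalization: Regionalization,
                       graph: AdjacencyGraph | None = None) -> ResponseTable:
    """Point responses with a targeted among-region variance fraction.

    Each point lands in a unit (uniformly at random over units), inherits
    that unit's region, and draws response = region effect + residual.  The
    region-effect variance solves the balanced one-way ANOVA expectation

        E[SSB] / E[SSB + SSW] = among_fraction_true,

    with E[SSB] = (k-1)σ² + n(1-1/k)σ_b² and E[SSW] = (n-k)σ², so the
    realized SSB share fluctuates around the target with Monte-Carlo error.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_points
    k = regionalization.k
    a = spec.among_fraction_true
    s2 = spec.residual_sd**2

    B = (k - 1) * s2
    C = (n - k) * s2
    A = n * (1.0 - 1.0 / k)
    var_b = max(0.0, (a * (B + C) - B) / (A * (1.0 - a)))
    effects = rng.normal(0.0, np.sqrt(var_b), size=k)

    unit_idx = rng.integers(0, regionalization.n_units, size=n)
    unit_ids = [regionalization.unit_id[i] for i in unit_idx]
    region0 = regionalization.label[unit_idx] - 1
    y = effects[region0] + rng.normal(0.0, spec.residual_sd, size=n)
    df = pd.DataFrame({
        "point_id": [f"p{i}" for i in range(n)],
        "unit_id": unit_ids,
        spec.response_name: y,
    })
    return ResponseTable(data=df)
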