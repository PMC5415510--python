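"""Clean raw geospatial variables and reduce them to the clustering feature space.

The pipeline is: (1) impute missing entries from the mean of each unit's
graph neighbors, iterated so later rounds can use earlier imputations,
with a column-mean fallback; (2) winsorize egregious outliers at a z-score
bound; (3) standardize each variable to mean 0, variance 1; (4) PCA,
keeping the minimal number of leading axes whose cumulative explained
variance reaches a threshold (default 85%), optionally whitened so every
retained axis contributes equally to Euclidean distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from .io import AdjacencyGraph, SpatialUnitTable


@dataclass
class PreprocessConfig:
    variance_threshold: float = 0.85
    outlier_z: float = 6.0
    impute_max_rounds: int = 10
    whiten: bool = True
    drop_units: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 < self.variance_threshold <= 1:
            raise ValueError("variance_threshold must be in (0, 1]")
        if self.outlier_z <= 0:
            raise ValueError("outlier_z must be positive")
        if self.impute_max_rounds < 1:
            raise ValueError("impute_max_rounds must be >= 1")


@dataclass
class FeatureEmbedding:
    """PCA scores used by all clustering: n units x m retained components."""

    unit_id: list[str]
    scores: np.ndarray
    explained_fraction: np.ndarray
    cumulative_fraction: float

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.explained_fraction = np.asarray(self.explained_fraction, dtype=float)
        if np.any(np.isnan(self.scores)):
            raise ValueError("embedding scores contain missing values")
        if np.any(np.diff(self.explained_fraction) > 1e-12):
            raise ValueError("explained fractions must be non-increasing")

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]

    @classmethod
    def from_matrix(cls, unit_id: list[str], scores: np.ndarray) -> "FeatureEmbedding":
        """Wrap an arbitrary feature matrix as an embedding (no PCA applied)."""
        scores = np.asarray(scores, dtype=float)
        var = scores.var(axis=0, ddof=1)
        total = var.sum()
        frac = var / total if total > 0 else np.full(scores.shape[1], 1.0 / scores.shape[1])
        order = np.argsort(frac)[::-1]
        return cls(
            unit_id=list(unit_id),
            scores=scores[:, order],
            explained_fraction=frac[order],
            cumulative_fraction=1.0,
        )


def winsorize_columns(X: np.ndarray, z: float) -> np.ndarray:
    """Clamp each column's values to mean ± z standard deviations.

    Clamping never moves a value across the column mean, so the sign of
    every deviation (relative to the mean used for clamping) is preserved.
    """
    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.clip(X, mu - z * sd, mu + z * sd)


def preprocess_features(table: SpatialUnitTable, graph: AdjacencyGraph,
                        config: PreprocessConfig | None = None) -> SpatialUnitTable:
    """Impute, winsorize and standardize the raw variable table.

    Missing values are replaced by the mean of the unit's graph-neighbors'
    known values for that variable, iterating up to ``impute_max_rounds`` so
    values imputed in one round can feed the next; any cell still missing
    falls back to the column mean.  Winsorizing clamps values with |z| >
    ``outlier_z`` to the z-bound (computed on the imputed column) rather
    than dropping the unit, which would silently change the contiguity
    graph.  Constant variables are dropped with a warning.
    """
    config = config or PreprocessConfig()
    keep = [i for i, u in enumerate(table.unit_id) if u not in set(config.drop_units)]
    unit_id = [table.unit_id[i] for i in keep]
    X = table.values[keep].copy()

    entirely_missing = np.isnan(X).all(axis=0)
    if entirely_missing.any():
        names = [table.variable_names[j] for j in np.flatnonzero(entirely_missing)]
        raise ValueError(f"variable(s) entirely missing: {names}")

    A = graph.to_sparse(order=unit_id)
    for _ in range(config.impute_max_rounds):
        missing = np.isnan(X)
        if not missing.any():
            break
        known = (~missing).astype(float)
        filled = np.where(missing, 0.0, X)
        neigh_sum = A @ filled
        neigh_cnt = A @ known
        with np.errstate(invalid="ignore", divide="ignore"):
            neigh_mean = neigh_sum / neigh_cnt
        fillable = missing & (neigh_cnt > 0)
        X[fillable] = neigh_mean[fillable]
    still = np.isnan(X)
    if still.any():
        col_mean = np.nanmean(X, axis=0)
        X[still] = np.broadcast_to(col_mean, X.shape)[still]

    X = winsorize_columns(X, config.outlier_z)

    mu = X.mean(axis=0)
    sd = X.std(axis=0, ddof=0)
    constant = sd < 1e-12
    if constant.all():
        raise ValueError("all variables are constant after imputation")
    if constant.any():
        dropped = [table.variable_names[j] for j in np.flatnonzero(constant)]
        warnings.warn(f"dropping constant variable(s): {dropped}", stacklevel=2)
    cols = np.flatnonzero(~constant)
    Z = (X[:, cols] - mu[cols]) / sd[cols]
    names = [table.variable_names[j] for j in cols]
    return SpatialUnitTable(
        unit_id=unit_id,
        values=Z,
        variable_names=names,
        themes={v: table.themes[v] for v in names},
        area=None if table.area is None else np.asarray(table.area)[keep],
    )


def pca_reduce(clean_table: SpatialUnitTable,
               config: PreprocessConfig | None = None) -> FeatureEmbedding:
    """PCA on the standardized table, keeping the minimal m components whose
    cumulative explained variance is at least the configured threshold.

    With ``whiten`` each retained score column is rescaled to sample
    variance 1 ("unweighted" axes: every retained component contributes
    equally to the distances the similarity kernel sees).
    """
    config = config or PreprocessConfig()
    X = clean_table.values
    if np.isnan(X).any():
        raise ValueError("pca_reduce requires a complete (imputed) table")
    n = X.shape[0]
    if n < 2:
        raise ValueError("need at least 2 units for PCA")

    pca = PCA(n_components=min(X.shape), svd_solver="full")
    scores = pca.fit_transform(X)
    ratio = pca.explained_variance_ratio_
    cum = np.cumsum(ratio)
    m = int(np.searchsorted(cum, config.variance_threshold - 1e-12) + 1)
    m = min(m, scores.shape[1])
    scores = scores[:, :m]
    if config.whiten:
        sd = scores.std(axis=0, ddof=1)
        sd[sd < 1e-15] = 1.0
        scores = scores / sd
    return FeatureEmbedding(
        unit_id=list(clean_table.unit_id),
        scores=scores,
        explained_fraction=ratio[:m],
        cumulative_fraction=float(cum[m - 1]),
    )
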