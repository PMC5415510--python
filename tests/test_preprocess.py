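import numpy as np
import pytest

from ecoregions import AdjacencyGraph, PreprocessConfig, SpatialUnitTable, pca_reduce, preprocess_features
from ecoregions.synth import lattice_graph


def _table(values, graph=None):
    values = np.asarray(values, dtype=float)
    n, p = values.shape
    ids = graph.unit_ids if graph is not None else [f"u{i}" for i in range(n)]
    return SpatialUnitTable(unit_id=list(ids), values=values,
                            variable_names=[f"v{j}" for j in range(p)])


def _chain(n):
    g = AdjacencyGraph(unit_ids=[f"u{i}" for i in range(n)])
    for i in range(n - 1):
        g.add_edge(f"u{i}", f"u{i+1}")
    return g


class TestImputation:
    def test_missing_value_gets_neighbor_mean(self):
        g = _chain(3)
        vals = [[2.0, 1.0], [np.nan, 2.0], [4.0, 3.0]]
        # disable winsorize/standardize effects on the check by recomputing
        clean = preprocess_features(_table(vals, g), g, PreprocessConfig())
        # u1's missing v0 imputed to mean(2, 4) = 3 -> after standardization the
        # column [2,3,4] maps to [-z,0,+z]: middle value must be the column mean
        assert clean.values[1, 0] == pytest.approx(0.0, abs=1e-10)

    def test_idempotent_on_complete_data(self):
        g = _chain(4)
        rng = np.random.default_rng(1)
        vals = rng.normal(size=(4, 3))
        clean1 = preprocess_features(_table(vals, g), g, PreprocessConfig())
        clean2 = preprocess_features(
            SpatialUnitTable(unit_id=clean1.unit_id,
                             values=clean1.values.copy(),
                             variable_names=clean1.variable_names),
            g, PreprocessConfig())
        np.testing.assert_allclose(clean2.values, clean1.values, atol=1e-10)

    def test_entirely_missing_variable_rejected(self):
        g = _chain(3)
        vals = [[1.0, np.nan], [2.0, np.nan], [3.0, np.nan]]
        with pytest.raises(ValueError, match="entirely missing"):
            preprocess_features(_table(vals, g), g, PreprocessConfig())

    def test_isolated_unit_falls_back_to_column_mean(self):
        g = AdjacencyGraph(unit_ids=["u0", "u1", "u2"])
        g.add_edge("u0", "u1")
        vals = [[1.0, 1.0], [3.0, 2.0], [np.nan, 3.0]]
        clean = preprocess_features(_table(vals, g), g, PreprocessConfig())
        # u2 has no neighbors: imputed to mean(1, 3) = 2, the column mean -> 0 after scaling
        assert clean.values[2, 0] == pytest.approx(0.0, abs=1e-10)


class TestWinsorize:
    def test_extreme_outlier_clamped_to_z_bound(self):
        n = 101
        g = _chain(n)
        col = np.zeros(n)
        col[-1] = 1000.0
        vals = np.column_stack([col, np.linspace(0, 1, n)])
        cfg = PreprocessConfig(outlier_z=6.0)
        clean = preprocess_features(_table(vals, g), g, cfg)

        # independent recomputation: clamp at mean+6sd, then standardize
        mu, sd = col.mean(), col.std()
        clamped = np.clip(col, mu - 6 * sd, mu + 6 * sd)
        assert clamped[-1] < 1000.0  # the outlier was actually clamped
        expected = (clamped - clamped.mean()) / clamped.std()
        np.testing.assert_allclose(clean.values[:, 0], expected, atol=1e-10)

    def test_winsorizing_preserves_deviation_sign(self, rng):
        from ecoregions.preprocess import winsorize_columns

        vals = rng.standard_t(df=2, size=(60, 4)) * 10
        clamped = winsorize_columns(vals, 1.5)
        signs_raw = np.sign(vals - vals.mean(axis=0))
        signs_clamped = np.sign(clamped - vals.mean(axis=0))
        agree = (signs_raw == signs_clamped) | (signs_clamped == 0) | (signs_raw == 0)
        assert agree.all()


class TestStandardize:
    def test_columns_have_zero_mean_unit_variance(self, rng):
        n = 50
        g = _chain(n)
        vals = rng.normal(loc=7.0, scale=3.0, size=(n, 5))
        clean = preprocess_features(_table(vals, g), g, PreprocessConfig())
        np.testing.assert_allclose(clean.values.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(clean.values.std(axis=0), 1.0, atol=1e-10)

    def test_constant_column_dropped_with_warning(self, rng):
        n = 20
        g = _chain(n)
        vals = np.column_stack([np.full(n, 3.0), rng.normal(size=n)])
        with pytest.warns(UserWarning, match="constant"):
            clean = preprocess_features(_table(vals, g), g, PreprocessConfig())
        assert clean.variable_names == ["v1"]

    def test_all_constant_rejected(self):
        g = _chain(5)
        with pytest.raises(ValueError, match="constant"):
            preprocess_features(_table(np.ones((5, 2)), g), g, PreprocessConfig())


class TestPCA:
    def test_component_count_from_eigenvalue_shares(self, rng):
        # construct data whose covariance eigenvalue shares are ~[.5,.3,.1,.1]
        n = 4000
        basis, _ = np.linalg.qr(rng.normal(size=(4, 4)))
        scales = np.sqrt(np.array([0.5, 0.3, 0.1, 0.1]))
        X = rng.normal(size=(n, 4)) * scales @ basis  # eigenvalue shares = scales^2
        t = SpatialUnitTable(unit_id=[f"u{i}" for i in range(n)], values=X,
                             variable_names=list("abcd"))
        emb = pca_reduce(t, PreprocessConfig(variance_threshold=0.85, whiten=False))
        assert emb.n_components == 3
        assert emb.cumulative_fraction >= 0.85

    def test_rank_one_signal_needs_single_component(self, rng):
        n = 200
        u = rng.normal(size=n)
        X = np.outer(u, [1.0, 2.0, -1.0]) + rng.normal(scale=1e-3, size=(n, 3))
        t = SpatialUnitTable(unit_id=[f"u{i}" for i in range(n)], values=X,
                             variable_names=list("abc"))
        emb = pca_reduce(t, PreprocessConfig(variance_threshold=0.85))
        assert emb.n_components == 1

    def test_retained_variance_matches_eigendecomposition(self, rng):
        n, p = 80, 6
        X = rng.normal(size=(n, p)) @ rng.normal(size=(p, p))
        X = (X - X.mean(0)) / X.std(0)
        t = SpatialUnitTable(unit_id=[f"u{i}" for i in range(n)], values=X,
                             variable_names=[f"v{j}" for j in range(p)])
        emb = pca_reduce(t, PreprocessConfig(variance_threshold=0.85, whiten=False))
        # oracle: eigendecomposition of the sample covariance
        evals = np.sort(np.linalg.eigvalsh(np.cov(X.T)))[::-1]
        shares = evals / evals.sum()
        m = int(np.argmax(np.cumsum(shares) >= 0.85)) + 1
        assert emb.n_components == m
        np.testing.assert_allclose(emb.explained_fraction, shares[:m], atol=1e-8)
        # retained scores reproduce at least the threshold share of variance
        assert emb.scores.var(axis=0, ddof=1).sum() / evals.sum() >= 0.85 - 1e-8

    def test_whitened_scores_unit_variance_and_uncorrelated(self, quadrant_embedding):
        _, emb = quadrant_embedding
        np.testing.assert_allclose(emb.scores.var(axis=0, ddof=1), 1.0, atol=1e-8)
        corr = np.corrcoef(emb.scores.T)
        np.testing.assert_allclose(corr - np.eye(corr.shape[0]), 0.0, atol=1e-8)


def test_drop_units_removes_rows_and_graph_still_aligns():
    g = lattice_graph(3, 3)
    rng = np.random.default_rng(3)
    vals = rng.normal(size=(9, 2))
    t = SpatialUnitTable(unit_id=list(g.unit_ids), values=vals,
                         variable_names=["a", "b"])
    clean = preprocess_features(t, g, PreprocessConfig(drop_units=["r0c0"]))
    assert clean.n_units == 8 and "r0c0" not in clean.unit_id
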