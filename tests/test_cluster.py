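import itertools

import numpy as np
import pytest
from scipy import sparse
from scipy.linalg import eigh
from sklearn.metrics import adjusted_rand_score

from ecoregions import AdjacencyGraph, ClusterConfig, cluster_regions, kmeans_min_ssw, spectral_embed
from ecoregions.evaluate import within_between_ss
from ecoregions.preprocess import FeatureEmbedding


def _random_connected_affinity(n, rng):
    """Random symmetric positive affinity with a guaranteed connected pattern."""
    W = rng.uniform(0.1, 1.0, size=(n, n))
    W = (W + W.T) / 2
    np.fill_diagonal(W, 1.0)
    mask = rng.uniform(size=(n, n)) < 0.5
    mask = mask | mask.T
    for i in range(n - 1):  # spanning path keeps it connected
        mask[i, i + 1] = mask[i + 1, i] = True
    np.fill_diagonal(mask, True)
    return W * mask


class TestSpectralEmbed:
    def test_matches_symmetric_normalized_oracle(self, rng):
        """Generalized eigenpairs L u = λ D u agree with the independent
        symmetric formulation D^{-1/2} L D^{-1/2} v = λ v, u = D^{-1/2} v."""
        for trial in range(5):
            S = _random_connected_affinity(8, rng)
            k = 4
            U = spectral_embed(S, k)

            d = S.sum(axis=1)
            L = np.diag(d) - S
            Dmh = np.diag(1.0 / np.sqrt(d))
            Lsym = Dmh @ L @ Dmh
            vals, V = np.linalg.eigh((Lsym + Lsym.T) / 2)
            U_oracle = Dmh @ V[:, :k]

            # compare up to per-column sign and scale
            for j in range(k):
                u, v = U[:, j], U_oracle[:, j]
                v = v / np.linalg.norm(v) * np.linalg.norm(u)
                err = min(np.abs(u - v).max(), np.abs(u + v).max())
                assert err < 1e-8

    def test_generalized_eigenvalues_match_dense_oracle(self, rng):
        S = _random_connected_affinity(8, rng)
        d = S.sum(axis=1)
        L = np.diag(d) - S
        vals_oracle = eigh(L, np.diag(d), eigvals_only=True)
        U = spectral_embed(S, 3)
        # Rayleigh quotients of returned vectors reproduce the eigenvalues
        for j in range(3):
            u = U[:, j]
            lam = (u @ L @ u) / (u @ np.diag(d) @ u)
            assert lam == pytest.approx(vals_oracle[j], abs=1e-8)

    def test_two_component_graph_has_double_zero_eigenvalue(self):
        """An exactly 2-component affinity: eigenvalue 0 with multiplicity 2
        and embedding columns constant within each component."""
        blockA = np.ones((3, 3))
        blockB = np.ones((4, 4))
        S = np.block([[blockA, np.zeros((3, 4))], [np.zeros((4, 3)), blockB]])
        U = spectral_embed(S, 2, allow_disconnected=True)
        d = S.sum(axis=1)
        L = np.diag(d) - S
        vals = eigh(L, np.diag(d), eigvals_only=True)
        assert vals[0] == pytest.approx(0.0, abs=1e-10)
        assert vals[1] == pytest.approx(0.0, abs=1e-10)
        assert vals[2] > 1e-6
        for j in range(2):
            assert np.ptp(U[:3, j]) < 1e-8   # constant on component A
            assert np.ptp(U[3:, j]) < 1e-8   # constant on component B

    def test_complete_graph_first_vector_constant(self):
        S = np.ones((6, 6))
        U = spectral_embed(S, 1)
        assert np.ptp(U[:, 0]) < 1e-10

    def test_disconnected_rejected_by_default(self):
        S = np.block([[np.ones((2, 2)), np.zeros((2, 2))],
                      [np.zeros((2, 2)), np.ones((2, 2))]])
        with pytest.raises(ValueError, match="isolated"):
            spectral_embed(S, 2)

    def test_sign_convention_deterministic(self, rng):
        S = _random_connected_affinity(8, rng)
        U1 = spectral_embed(S, 3)
        U2 = spectral_embed(S, 3)
        np.testing.assert_array_equal(U1, U2)
        for j in range(3):
            assert U1[np.argmax(np.abs(U1[:, j])), j] > 0


def _brute_force_min_ssw(X, k):
    """Exhaustive minimum SSW over all k-labelings (label-symmetry reduced by
    pinning point 0 to cluster 0); vectorized over chunks of assignments."""
    n = len(X)
    sq = (X**2).sum()
    best = np.inf
    rest = np.array(list(itertools.product(range(k), repeat=n - 1)), dtype=np.int8)
    labels = np.concatenate([np.zeros((rest.shape[0], 1), dtype=np.int8), rest], axis=1)
    for chunk in np.array_split(labels, max(1, len(labels) // 200_000)):
        ssw = np.full(chunk.shape[0], sq)
        valid = np.ones(chunk.shape[0], dtype=bool)
        for c in range(k):
            mask = (chunk == c)
            cnt = mask.sum(axis=1)
            valid &= cnt > 0
            sums = mask.astype(float) @ X
            with np.errstate(invalid="ignore", divide="ignore"):
                ssw -= np.where(cnt > 0, (sums**2).sum(axis=1) / cnt, 0.0)
        m = ssw[valid].min() if valid.any() else np.inf
        best = min(best, m)
    return best


class TestKMeans:
    def test_k_equals_n_gives_zero_objective(self, rng):
        X = rng.normal(size=(6, 2))
        labels, obj = kmeans_min_ssw(X, k=6, restarts=5, seed=0)
        assert obj == pytest.approx(0.0, abs=1e-10)
        assert len(np.unique(labels)) == 6

    def test_k_one_gives_total_ss(self, rng):
        X = rng.normal(size=(10, 3))
        _, obj = kmeans_min_ssw(X, k=1, restarts=1, seed=0)
        total = ((X - X.mean(axis=0)) ** 2).sum()
        assert obj == pytest.approx(total, rel=1e-10)

    def test_four_blobs_attain_exhaustive_minimum(self, rng):
        """12 points in 4 separated planar blobs: restarted k-means reaches the
        exact exhaustive-search minimum SSW over all 4-partitions."""
        centers = np.array([[0, 0], [10, 0], [0, 10], [10, 10]], dtype=float)
        X = np.vstack([c + rng.normal(scale=0.5, size=(3, 2)) for c in centers])
        labels, obj = kmeans_min_ssw(X, k=4, restarts=50, seed=1)
        truth = np.repeat(np.arange(4), 3)
        assert adjusted_rand_score(truth, labels) == 1.0
        oracle = _brute_force_min_ssw(X, 4)
        assert obj == pytest.approx(oracle, rel=1e-10)

    def test_best_objective_non_increasing_in_restarts(self, rng):
        X = rng.normal(size=(40, 3))
        objs = [kmeans_min_ssw(X, k=5, restarts=r, seed=7)[1] for r in (1, 3, 10, 25)]
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_k_above_n_rejected(self, rng):
        with pytest.raises(ValueError, match="exceeds"):
            kmeans_min_ssw(rng.normal(size=(3, 2)), k=4, restarts=1, seed=0)


def _barbell():
    """Two 5-cliques joined by a single bridge edge."""
    ids = [f"n{i}" for i in range(10)]
    g = AdjacencyGraph(unit_ids=ids)
    for block in (range(5), range(5, 10)):
        for i, j in itertools.combinations(block, 2):
            g.add_edge(ids[i], ids[j])
    g.add_edge(ids[4], ids[5])
    return g, ids


def _ncut(S, side_mask):
    """Normalized cut of a 2-partition of affinity S."""
    d = S.sum(axis=1)
    cut = S[side_mask][:, ~side_mask].sum()
    volA, volB = d[side_mask].sum(), d[~side_mask].sum()
    return cut / volA + cut / volB


class TestClusterRegions:
    def test_ssc_recovers_barbell_cliques(self):
        """SSC on a barbell with uniform features finds the minimum normalized
        cut (the two cliques), verified against 2-partition brute force."""
        g, ids = _barbell()
        emb = FeatureEmbedding.from_matrix(ids, np.ones((10, 2)))
        cfg = ClusterConfig(k=2, method="SSC", delta=1, restarts=20, seed=3)
        reg = cluster_regions(emb, g, cfg)

        S = (g.to_sparse(order=ids) + sparse.identity(10)).toarray()
        best_mask, best_val = None, np.inf
        for bits in range(1, 2**9):  # node 0 pinned to side A
            mask = np.array([True] + [(bits >> i) & 1 == 0 for i in range(9)])
            if mask.all():
                continue
            v = _ncut(S, mask)
            if v < best_val:
                best_val, best_mask = v, mask
        assert set(np.flatnonzero(best_mask)) == set(range(5))  # oracle: cliques
        assert adjusted_rand_score(best_mask, reg.label) == 1.0

    def test_random_reproducible_and_no_empty_label(self):
        cfg = ClusterConfig(k=3, method="RANDOM", seed=5)
        r1 = cluster_regions(None, None, cfg, unit_ids=[f"u{i}" for i in range(10)])
        r2 = cluster_regions(None, None, cfg, unit_ids=[f"u{i}" for i in range(10)])
        assert np.array_equal(r1.label, r2.label)
        assert set(np.unique(r1.label)) == {1, 2, 3}

    def test_kmeans_ignores_graph(self, rng):
        X = np.vstack([rng.normal(size=(10, 2)), rng.normal(loc=8, size=(10, 2))])
        ids = [f"u{i}" for i in range(20)]
        emb = FeatureEmbedding.from_matrix(ids, X)
        g1 = AdjacencyGraph(unit_ids=ids)
        for i in range(19):
            g1.add_edge(ids[i], ids[i + 1])
        g2 = AdjacencyGraph(unit_ids=ids)
        for i in range(0, 18, 2):
            g2.add_edge(ids[i], ids[i + 2])
            g2.add_edge(ids[i + 1], ids[i + 3])
        cfg = ClusterConfig(k=2, method="KMEANS", restarts=10, seed=2)
        r1 = cluster_regions(emb, g1, cfg)
        r2 = cluster_regions(emb, g2, cfg)
        assert np.array_equal(r1.label, r2.label)

    def test_ssc_planted_quadrant_recovery(self, quadrant_landscape, quadrant_embedding):
        """20x20 lattice, 4 planted contiguous regions, effect size 3:
        SSC(δ=2, k=4) recovers the planted partition (ARI >= 0.9)."""
        _, graph, truth = quadrant_landscape
        _, emb = quadrant_embedding
        cfg = ClusterConfig(k=4, method="SSC", delta=2, restarts=50, seed=7)
        reg = cluster_regions(emb, graph, cfg)
        assert adjusted_rand_score(truth, reg.label) >= 0.9

    def test_ssc_on_uniform_features_reduces_to_sc(self):
        g, ids = _barbell()
        emb = FeatureEmbedding.from_matrix(ids, np.ones((10, 3)))
        ssc = cluster_regions(emb, g, ClusterConfig(k=2, method="SSC", delta=1,
                                                    restarts=10, seed=4))
        sc = cluster_regions(emb, g, ClusterConfig(k=2, method="SC", delta=1,
                                                   restarts=10, seed=4))
        assert adjusted_rand_score(ssc.label, sc.label) == 1.0

    def test_determinism_all_methods(self, quadrant_landscape, quadrant_embedding):
        _, graph, _ = quadrant_landscape
        _, emb = quadrant_embedding
        for method, delta in (("SSC", 2), ("SC", 2), ("KMEANS", None), ("RANDOM", None)):
            cfg = ClusterConfig(k=4, method=method, delta=delta, restarts=5, seed=11)
            a = cluster_regions(emb, graph, cfg)
            b = cluster_regions(emb, graph, cfg)
            assert np.array_equal(a.label, b.label), method

    def test_method_delta_mismatch_rejected(self):
        with pytest.raises(ValueError, match="delta"):
            ClusterConfig(k=2, method="SSC", delta=None)
        with pytest.raises(ValueError, match="delta"):
            ClusterConfig(k=2, method="KMEANS", delta=3)

    def test_labels_are_one_to_k_with_no_empty_region(self, quadrant_landscape,
                                                      quadrant_embedding):
        _, graph, _ = quadrant_landscape
        _, emb = quadrant_embedding
        reg = cluster_regions(emb, graph, ClusterConfig(k=6, method="SSC", delta=2,
                                                        restarts=10, seed=0))
        assert set(np.unique(reg.label)) == set(range(1, 7))
        ssw, _, _ = within_between_ss(emb.scores, reg.label)
        assert np.isfinite(ssw)
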