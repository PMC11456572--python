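import networkx as nx
import numpy as np
import pytest

from psmdnet.graphmetrics import (
    assortativity,
    clustering_and_local_efficiency,
    characteristic_path_length,
    distance_matrix,
    global_efficiency,
    hierarchy,
    modularity,
    nodal_clustering,
    normalize_weights,
    normalized_metrics,
    null_ensemble,
)

from _oracles import (
    brute_char_path_length,
    brute_global_efficiency,
    brute_modularity_max,
    brute_nodal_clustering,
    newman_assortativity,
)


def K(n):
    W = np.ones((n, n)) - np.eye(n)
    return W


def path_graph(n):
    W = np.zeros((n, n))
    for i in range(n - 1):
        W[i, i + 1] = W[i + 1, i] = 1.0
    return W


class TestNormalizeAndDistances:
    def test_normalize(self):
        W = np.array([[0, 2.0], [2.0, 0]])
        assert normalize_weights(W).max() == 1.0
        with pytest.raises(ValueError):
            normalize_weights(np.zeros((3, 3)))

    def test_k4_distances(self):
        D = distance_matrix(K(4))
        off = D[~np.eye(4, dtype=bool)]
        assert np.allclose(off, 1.0)

    def test_path_distances(self):
        D = distance_matrix(path_graph(3))
        assert D[0, 2] == pytest.approx(2.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(0)
        W = rng.uniform(0, 1, (6, 6))
        W = np.triu(W, 1)
        W = W + W.T
        e1 = global_efficiency(normalize_weights(W))
        e2 = global_efficiency(normalize_weights(2.0 * W))
        assert e1 == pytest.approx(e2, rel=1e-12)


class TestGlobalEfficiency:
    def test_k4(self):
        assert global_efficiency(K(4)) == pytest.approx(1.0)

    def test_path3(self):
        assert global_efficiency(path_graph(3)) == pytest.approx(5.0 / 6.0)

    def test_edgeless(self):
        assert global_efficiency(np.zeros((4, 4))) == 0.0


class TestClustering:
    def test_triangle(self):
        C, _ = clustering_and_local_efficiency(K(3))
        assert C == pytest.approx(1.0)

    def test_star(self):
        W = np.zeros((5, 5))
        W[0, 1:] = W[1:, 0] = 1.0
        C, eloc = clustering_and_local_efficiency(W)
        assert C == 0.0
        assert eloc == 0.0

    def test_k4(self):
        C, eloc = clustering_and_local_efficiency(K(4))
        assert C == pytest.approx(1.0)
        assert eloc == pytest.approx(1.0)


class TestAssortativity:
    def test_p4_newman(self):
        assert assortativity(path_graph(4)) == pytest.approx(-0.5)

    def test_regular_errors(self):
        ring = np.zeros((5, 5))
        for i in range(5):
            ring[i, (i + 1) % 5] = ring[(i + 1) % 5, i] = 1.0
        with pytest.raises(ValueError, match="assortativity"):
            assortativity(ring)

    def test_bounded(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            G = nx.gnp_random_graph(8, 0.5, seed=int(rng.integers(1e6)))
            if G.number_of_edges() < 2:
                continue
            W = nx.to_numpy_array(G)
            W *= rng.uniform(0.2, 1.0, W.shape)
            W = np.triu(W, 1)
            W = W + W.T
            try:
                r = assortativity(W)
            except ValueError:
                continue
            assert -1.0 - 1e-9 <= r <= 1.0 + 1e-9


class TestModularity:
    def test_two_cliques(self):
        W = np.zeros((6, 6))
        W[np.ix_([0, 1, 2], [0, 1, 2])] = K(3)
        W[np.ix_([3, 4, 5], [3, 4, 5])] = K(3)
        assert modularity(W, seed=0) == pytest.approx(0.5)

    def test_complete_graph(self):
        assert modularity(K(5), seed=0) == pytest.approx(0.0, abs=1e-12)

    def test_edgeless_errors(self):
        with pytest.raises(ValueError):
            modularity(np.zeros((3, 3)), seed=0)


class TestHierarchy:
    def test_exact_power_law(self):
        """Synthetic log-log relation C = k^(-0.5) recovered exactly."""
        k = np.array([2.0, 3, 4, 6])
        C = k**-0.5
        logk, logc = np.log(k), np.log(C)
        slope = np.polyfit(logk, logc, 1)[0]
        assert -slope == pytest.approx(0.5, abs=1e-9)
        # and through the public API on a graph whose C/k follow a power law
        W = np.zeros((7, 7))
        # star-of-triangles structure gives varying k with C > 0
        for i, j in [(0, 1), (1, 2), (0, 2), (0, 3), (3, 4), (0, 4),
                     (0, 5), (5, 6), (0, 6), (2, 3)]:
            W[i, j] = W[j, i] = 1.0
        beta = hierarchy(W)
        assert np.isfinite(beta)

    def test_constant_degree_errors(self):
        with pytest.raises(ValueError, match="hierarchy"):
            hierarchy(K(4))


class TestAgainstBruteForce:
    """Spot checks on random small weighted graphs (full sweep in acceptance)."""

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_random_graph(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 7))
        while True:
            G = nx.gnp_random_graph(n, 0.6, seed=int(rng.integers(1e6)))
            if nx.is_connected(G):
                break
        W = nx.to_numpy_array(G)
        W *= rng.uniform(0.2, 1.0, (n, n))
        W = np.triu(W, 1)
        W = W + W.T
        Wn = normalize_weights(W)
        assert global_efficiency(Wn) == pytest.approx(
            brute_global_efficiency(Wn), rel=1e-9
        )
        assert characteristic_path_length(Wn) == pytest.approx(
            brute_char_path_length(Wn), rel=1e-9
        )
        assert np.allclose(nodal_clustering(Wn), brute_nodal_clustering(Wn))
        assert modularity(Wn, seed=0) == pytest.approx(
            brute_modularity_max(Wn), abs=1e-9
        )
        try:
            r = assortativity(Wn)
            assert r == pytest.approx(newman_assortativity(Wn), rel=1e-9)
        except ValueError:
            pass

    def test_node_relabeling_invariance(self):
        rng = np.random.default_rng(9)
        W = rng.uniform(0, 1, (7, 7))
        W = np.triu(W, 1)
        W = W + W.T
        perm = rng.permutation(7)
        Wp = W[np.ix_(perm, perm)]
        assert global_efficiency(W) == pytest.approx(global_efficiency(Wp))
        c1, e1 = clustering_and_local_efficiency(W)
        c2, e2 = clustering_and_local_efficiency(Wp)
        assert c1 == pytest.approx(c2)
        assert e1 == pytest.approx(e2)


class TestNullEnsemble:
    def test_degree_sequences_preserved(self):
        rng = np.random.default_rng(2)
        G = nx.gnp_random_graph(12, 0.3, seed=7)
        W = nx.to_numpy_array(G) * rng.uniform(0.2, 1.0, (12, 12))
        W = np.triu(W, 1)
        W = W + W.T
        deg0 = sorted(((W > 0).sum(axis=1)).tolist())
        for Wnull in null_ensemble(W, n_nulls=10, seed=3):
            assert sorted(((Wnull > 0).sum(axis=1)).tolist()) == deg0
            # weights are a permutation of the originals
            assert np.allclose(
                sorted(Wnull[np.triu_indices(12, 1)][Wnull[np.triu_indices(12, 1)] > 0]),
                sorted(W[np.triu_indices(12, 1)][W[np.triu_indices(12, 1)] > 0]),
            )

    def test_sigma_identity_and_lattice_gamma(self):
        # ring lattice: high clustering relative to rewired nulls
        n = 20
        W = np.zeros((n, n))
        for i in range(n):
            for d in (1, 2):
                W[i, (i + d) % n] = W[(i + d) % n, i] = 1.0
        gamma, lam, sigma = normalized_metrics(W, n_nulls=30, seed=0)
        assert sigma == pytest.approx(gamma / lam, rel=1e-12)
        assert gamma > 1.0

    def test_seeded_reproducible(self):
        G = nx.gnp_random_graph(10, 0.4, seed=5)
        W = nx.to_numpy_array(G)
        a = normalized_metrics(W, n_nulls=10, seed=11)
        b = normalized_metrics(W, n_nulls=10, seed=11)
        assert a == b
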