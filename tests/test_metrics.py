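"""Graph topology against brute-force and networkx oracles, and the
degree-preserving null model."""

import itertools
import warnings

import networkx as nx
import numpy as np
import pytest

import dynconn as dc
from conftest import random_binary_graph


def graph_from_edges(n, edges):
    a = np.zeros((n, n), dtype=int)
    for i, j in edges:
        a[i, j] = a[j, i] = 1
    return dc.BinaryGraph(a)


def brute_clustering(g):
    """Triple-enumeration oracle for local clustering."""
    a = g.adjacency
    n = g.n_nodes
    local = np.zeros(n)
    for i in range(n):
        nbrs = np.flatnonzero(a[i])
        k = len(nbrs)
        if k < 2:
            continue
        tri = sum(a[u, v] for u, v in itertools.combinations(nbrs, 2))
        local[i] = tri / (k * (k - 1) / 2)
    return local.mean(), local


def floyd_warshall_lp(g):
    """All-pairs shortest paths oracle; mean over connected pairs."""
    n = g.n_nodes
    d = np.full((n, n), np.inf)
    np.fill_diagonal(d, 0)
    d[g.adjacency > 0] = 1
    for k in range(n):
        d = np.minimum(d, d[:, [k]] + d[[k], :])
    iu = np.triu_indices(n, 1)
    vals = d[iu][np.isfinite(d[iu])]
    return vals.mean()


def brute_assortativity(g):
    deg = g.adjacency.sum(1)
    i, j = np.nonzero(np.triu(g.adjacency, 1))
    x = np.concatenate([deg[i], deg[j]]).astype(float)
    y = np.concatenate([deg[j], deg[i]]).astype(float)
    if x.std() == 0:
        return np.nan
    return np.corrcoef(x, y)[0, 1]


class TestClosedFormExamples:
    def test_sparsity_extremes_and_ring(self):
        k5 = graph_from_edges(5, itertools.combinations(range(5), 2))
        assert dc.sparsity(k5) == 1.0
        assert dc.sparsity(dc.BinaryGraph(np.zeros((5, 5)))) == 0.0
        ring6 = graph_from_edges(6, [(i, (i + 1) % 6) for i in range(6)])
        assert dc.sparsity(ring6) == pytest.approx(6 / 15)

    def test_sparsity_strictly_monotone_in_edges(self):
        g = graph_from_edges(5, [(0, 1), (1, 2)])
        g2 = graph_from_edges(5, [(0, 1), (1, 2), (2, 3)])
        assert dc.sparsity(g2) > dc.sparsity(g)

    def test_clustering_complete_and_star(self):
        k4 = graph_from_edges(4, itertools.combinations(range(4), 2))
        assert dc.clustering_coefficient(k4)[0] == pytest.approx(1.0)
        star = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        assert dc.clustering_coefficient(star)[0] == 0.0

    def test_path_length_examples(self):
        k4 = graph_from_edges(4, itertools.combinations(range(4), 2))
        assert dc.characteristic_path_length(k4)[0] == 1.0
        p4 = graph_from_edges(4, [(0, 1), (1, 2), (2, 3)])
        assert dc.characteristic_path_length(p4)[0] == pytest.approx(10 / 6)
        two_k3 = graph_from_edges(6, [(0, 1), (1, 2), (0, 2), (3, 4), (4, 5), (3, 5)])
        lp, ncomp, largest = dc.characteristic_path_length(two_k3)
        assert lp == 1.0 and ncomp == 2 and largest == 3

    def test_no_edges_rejected(self):
        with pytest.raises(ValueError):
            dc.characteristic_path_length(dc.BinaryGraph(np.zeros((4, 4))))

    def test_star_assortativity_and_regular_undefined(self):
        star = graph_from_edges(4, [(0, 1), (0, 2), (0, 3)])
        assert dc.assortativity(star) == pytest.approx(-1.0)
        ring = graph_from_edges(5, [(i, (i + 1) % 5) for i in range(5)])
        assert np.isnan(dc.assortativity(ring))

    def test_degree_star_and_handshake(self):
        star = graph_from_edges(5, [(0, i) for i in range(1, 5)])
        assert list(dc.degree_centrality(star)) == [4, 1, 1, 1, 1]
        rng = np.random.default_rng(0)
        g = random_binary_graph(rng, 15, 0.3)
        assert dc.degree_centrality(g).sum() == 2 * g.n_edges


class TestOracleEquivalence:
    @pytest.mark.parametrize("n,p,count", [(8, 0.4, 400), (12, 0.3, 600)])
    def test_random_graphs_match_brute_force_and_networkx(self, n, p, count):
        rng = np.random.default_rng(42)
        checked = 0
        while checked < count:
            g = random_binary_graph(rng, n, p)
            if g.n_edges < 2:
                continue
            checked += 1
            cp, local = dc.clustering_coefficient(g)
            bcp, blocal = brute_clustering(g)
            assert cp == pytest.approx(bcp, abs=1e-12)
            assert np.allclose(local, blocal, atol=1e-12)
            assert dc.characteristic_path_length(g)[0] == pytest.approx(
                floyd_warshall_lp(g), abs=1e-12)
            a, ba = dc.assortativity(g), brute_assortativity(g)
            assert (np.isnan(a) and np.isnan(ba)) or a == pytest.approx(ba, abs=1e-12)
            assert np.array_equal(dc.degree_centrality(g), g.adjacency.sum(1))
            # independent cross-check against networkx on a subsample
            if checked % 50 == 0:
                G = nx.from_numpy_array(g.adjacency)
                assert cp == pytest.approx(nx.average_clustering(G), abs=1e-12)
                if nx.is_connected(G):
                    assert dc.characteristic_path_length(g)[0] == pytest.approx(
                        nx.average_shortest_path_length(G), abs=1e-12)

    def test_relabeling_invariance(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            g = random_binary_graph(rng, 10, 0.4)
            if g.n_edges < 2:
                continue
            perm = rng.permutation(10)
            h = dc.BinaryGraph(g.adjacency[np.ix_(perm, perm)])
            assert dc.sparsity(g) == dc.sparsity(h)
            assert dc.clustering_coefficient(g)[0] == pytest.approx(
                dc.clustering_coefficient(h)[0], abs=1e-12)
            assert dc.characteristic_path_length(g)[0] == pytest.approx(
                dc.characteristic_path_length(h)[0], abs=1e-12)


class TestMaslovSneppen:
    def test_degree_sequence_preserved_many_trials(self):
        rng = np.random.default_rng(1)
        attempts = 0
        for k in range(120):
            n = int(rng.integers(8, 25))
            g = random_binary_graph(rng, n, float(rng.uniform(0.15, 0.6)))
            if g.n_edges < 2:
                continue
            attempts += 10 * g.n_edges
            r = dc.maslov_sneppen_rewire(g, swaps_per_edge=10, seed=int(rng.integers(2**31)))
            assert np.array_equal(r.adjacency.sum(1), g.adjacency.sum(1))
            assert np.all(np.diag(r.adjacency) == 0)
            assert np.array_equal(r.adjacency, r.adjacency.T)
        assert attempts > 10_000  # the ensemble covers >1e4 swap attempts

    def test_triangle_returned_unchanged(self):
        k3 = graph_from_edges(3, [(0, 1), (1, 2), (0, 2)])
        with pytest.warns(UserWarning):
            r = dc.maslov_sneppen_rewire(k3, 10, 0)
        assert np.array_equal(r.adjacency, k3.adjacency)

    def test_rewiring_destroys_lattice_clustering(self):
        # ring lattice with k=4 neighbours: high Cp; nulls must average lower
        n = 20
        edges = [(i, (i + d) % n) for i in range(n) for d in (1, 2)]
        g = graph_from_edges(n, edges)
        cp0 = dc.clustering_coefficient(g)[0]
        cps = [dc.clustering_coefficient(dc.maslov_sneppen_rewire(g, 10, s))[0]
               for s in range(100)]
        assert np.mean(cps) < cp0


class TestNormalizedMetrics:
    def test_identity_ensemble_gives_unity(self):
        rng = np.random.default_rng(2)
        g = random_binary_graph(rng, 12, 0.4)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            gamma, lam, sigma, _ = dc.normalized_metrics(g, n_rand=5, swaps_per_edge=0)
        assert gamma == pytest.approx(1.0, abs=1e-12)
        assert lam == pytest.approx(1.0, abs=1e-12)
        assert sigma == pytest.approx(1.0, abs=1e-12)

    def test_erdos_renyi_self_consistency(self):
        # a random graph is its own null: gamma ~ lambda ~ sigma ~ 1
        rng = np.random.default_rng(3)
        g = random_binary_graph(rng, 100, 0.2)
        gamma, lam, sigma, _ = dc.normalized_metrics(g, n_rand=100, seed=5)
        for value in (gamma, lam, sigma):
            assert abs(value - 1.0) < 0.1

    def test_watts_strogatz_small_world(self):
        G = nx.watts_strogatz_graph(60, 6, 0.1, seed=4)
        g = dc.BinaryGraph(nx.to_numpy_array(G))
        gamma, lam, sigma, _ = dc.normalized_metrics(g, n_rand=30, seed=6)
        assert sigma > 1.0

    def test_structural_preset_is_small_world_regime(self, preset):
        parc, truth = preset
        g = dc.BinaryGraph(truth.structural_weights > 0)
        gamma, lam, sigma, _ = dc.normalized_metrics(g, n_rand=50, seed=7)
        assert sigma > 1.0 and gamma > 1.0 and abs(lam - 1.0) < 0.25


class TestWeightedMetrics:
    def test_uniform_weight_reduction(self):
        w = np.zeros((4, 4))
        for i, j in [(0, 1), (1, 2), (2, 0), (2, 3)]:
            w[i, j] = w[j, i] = 0.5
        cpw, lpw, strength = dc.weighted_metrics(dc.WeightedGraph(w))
        g = dc.BinaryGraph(w > 0)
        assert cpw == pytest.approx(dc.clustering_coefficient(g)[0])
        assert lpw == pytest.approx(dc.characteristic_path_length(g)[0] / 0.5)

    def test_strength_equals_degree_for_unit_weights(self):
        rng = np.random.default_rng(8)
        g = random_binary_graph(rng, 10, 0.4)
        _, _, strength = dc.weighted_metrics(dc.WeightedGraph(g.adjacency.astype(float)))
        assert np.allclose(strength, dc.degree_centrality(g))

    def test_matches_networkx_onnela_and_dijkstra(self):
        rng = np.random.default_rng(9)
        w = np.zeros((6, 6))
        iu, ju = dc.edge_index(6)
        mask = rng.random(iu.size) < 0.6
        w[iu[mask], ju[mask]] = rng.uniform(0.2, 1.0, mask.sum())
        w = w + w.T
        cpw, lpw, _ = dc.weighted_metrics(dc.WeightedGraph(w))
        G = nx.from_numpy_array(w)
        assert cpw == pytest.approx(nx.average_clustering(G, weight="weight"), abs=1e-12)
        for u, v, d in G.edges(data=True):
            d["length"] = 1.0 / d["weight"]
        dists = dict(nx.all_pairs_dijkstra_path_length(G, weight="length"))
        vals = [dists[i][j] for i in range(6) for j in range(i + 1, 6) if j in dists[i]]
        assert lpw == pytest.approx(np.mean(vals), abs=1e-12)
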