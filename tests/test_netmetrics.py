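"""Graph measures, model degree laws, subsampling, and the decay fit."""

import itertools

import networkx as nx
import numpy as np
import pytest

from wavecon.connectivity import Connection, FunctionalNetwork
from wavecon.netmetrics import (
    DecayFit,
    SubsampleSpec,
    assortativity,
    chi2_compare,
    clustering_global,
    degree_distribution,
    disconnected_count,
    efficiency,
    fit_decay,
    model_degree_distributions,
    subsample_metrics,
    to_graph,
)

from _oracles import brute_assortativity, brute_clustering, brute_efficiency


def _graph(n, edges):
    g = nx.Graph()
    g.add_nodes_from(range(n))
    g.add_edges_from(edges)
    return g


def _net(n, edges, directed=None, ratios=None, positions=None, band="HFC"):
    conns = []
    for idx, (i, j) in enumerate(edges):
        is_dir = bool(directed[idx]) if directed is not None else False
        conns.append(
            Connection(
                pair=(i, j), band=band, peak_freq=200.0, peak_delay=0.0,
                peak_power=float(ratios[idx]) if ratios is not None else 2.0,
                threshold_power=1.0, directed=is_dir,
                direction="I->J" if is_dir else "bidirectional",
            )
        )
    return FunctionalNetwork(
        nodes=tuple(range(n)), edges=tuple(conns), band=band,
        positions=positions or {},
    )


class TestClustering:
    def test_complete_graph_is_one(self):
        assert clustering_global(nx.complete_graph(5)) == 1.0

    def test_star_graph_is_zero(self):
        assert clustering_global(nx.star_graph(4)) == 0.0

    def test_triangle_with_pendant(self):
        g = _graph(4, [(0, 1), (1, 2), (0, 2), (0, 3)])
        adj = nx.to_numpy_array(g)
        assert clustering_global(g) == pytest.approx(brute_clustering(adj))

    def test_no_qualifying_node_is_nan(self):
        assert np.isnan(clustering_global(_graph(3, [(0, 1)])))


class TestEfficiency:
    def test_complete_graph_is_one(self):
        assert efficiency(nx.complete_graph(6)) == pytest.approx(1.0)

    def test_three_node_path(self):
        # ordered pairs: four at distance 1, two at distance 2 -> 5/6
        assert efficiency(_graph(3, [(0, 1), (1, 2)])) == pytest.approx(5 / 6)

    def test_empty_graph_is_zero(self):
        assert efficiency(_graph(5, [])) == 0.0

    def test_nondecreasing_under_edge_addition(self, rng):
        g = nx.gnp_random_graph(12, 0.15, seed=3)
        before = efficiency(g)
        missing = list(nx.non_edges(g))
        g.add_edge(*missing[rng.integers(len(missing))])
        assert efficiency(g) >= before


class TestAssortativity:
    def test_star_graph_is_minus_one(self):
        assert assortativity(nx.star_graph(4)) == pytest.approx(-1.0)

    def test_complete_graph_undefined(self):
        assert np.isnan(assortativity(nx.complete_graph(4)))

    def test_two_disjoint_edges_undefined(self):
        assert np.isnan(assortativity(_graph(4, [(0, 1), (2, 3)])))

    def test_matches_networkx_on_random_graph(self):
        g = nx.gnp_random_graph(30, 0.12, seed=5)
        assert assortativity(g) == pytest.approx(
            nx.degree_assortativity_coefficient(g), abs=1e-10
        )


class TestBruteForceEquivalence:
    """All measures agree with naive reimplementations on small graphs."""

    def test_exhaustive_five_node_graphs(self):
        pairs = list(itertools.combinations(range(5), 2))
        for mask in range(1 << len(pairs)):
            edges = [pairs[b] for b in range(len(pairs)) if mask >> b & 1]
            g = _graph(5, edges)
            adj = nx.to_numpy_array(g)
            assert disconnected_count(g) == int((adj.sum(1) == 0).sum())
            c_ours, c_brute = clustering_global(g), brute_clustering(adj)
            assert (np.isnan(c_ours) and np.isnan(c_brute)) or c_ours == pytest.approx(c_brute)
            assert efficiency(g) == pytest.approx(brute_efficiency(adj))
            a_ours, a_brute = assortativity(g), brute_assortativity(adj)
            assert (np.isnan(a_ours) and np.isnan(a_brute)) or a_ours == pytest.approx(a_brute)

    def test_random_six_node_graphs(self, rng):
        pairs = list(itertools.combinations(range(6), 2))
        for _ in range(300):
            mask = rng.integers(0, 1 << len(pairs))
            edges = [pairs[b] for b in range(len(pairs)) if mask >> b & 1]
            g = _graph(6, edges)
            adj = nx.to_numpy_array(g)
            assert efficiency(g) == pytest.approx(brute_efficiency(adj))
            c_ours, c_brute = clustering_global(g), brute_clustering(adj)
            assert (np.isnan(c_ours) and np.isnan(c_brute)) or c_ours == pytest.approx(c_brute)
            a_ours, a_brute = assortativity(g), brute_assortativity(adj)
            assert (np.isnan(a_ours) and np.isnan(a_brute)) or a_ours == pytest.approx(a_brute)


class TestDegreeDistribution:
    def test_edgeless_network_is_all_zero_degree(self):
        dist = degree_distribution([_net(4, [])])
        assert dist[0] == 1.0

    def test_sums_to_one(self):
        net = _net(6, [(0, 1), (2, 3), (1, 2)])
        assert degree_distribution([net]).sum() == pytest.approx(1.0, abs=1e-12)

    def test_directed_edges_count_only_source(self):
        # A->B, A->C: out-degrees {2, 0, 0}
        net = _net(3, [(0, 1), (0, 2)], directed=[True, True])
        dist = degree_distribution([net])
        assert dist[0] == pytest.approx(2 / 3)
        assert dist[2] == pytest.approx(1 / 3)

    def test_bidirectional_edges_count_both_endpoints(self):
        net = _net(3, [(0, 1)], directed=[False])
        dist = degree_distribution([net])
        assert dist[1] == pytest.approx(2 / 3)
        assert dist[0] == pytest.approx(1 / 3)


class TestModelDegreeLaws:
    def test_binomial_mean_and_normalization(self):
        models = model_degree_distributions(n=100, p=0.01, n_parents=2,
                                            n_subsamples=2, seed=0)
        k = np.arange(100)
        assert (models["random"] * k).sum() == pytest.approx(99 * 0.01, rel=1e-9)
        for law in models.values():
            assert law.sum() == pytest.approx(1.0, abs=1e-9)

    def test_exponential_law_mean_matches_density(self):
        models = model_degree_distributions(n=100, p=0.02, n_parents=2,
                                            n_subsamples=2, seed=0)
        k = np.arange(100)
        assert (models["exponential"] * k).sum() == pytest.approx(99 * 0.02, rel=1e-6)

    def test_binomial_matches_er_simulation(self, rng):
        n, p = 40, 0.05
        models = model_degree_distributions(n=n, p=p, n_parents=2,
                                            n_subsamples=2, seed=0)
        hist = np.zeros(n)
        reps = 300
        for s in range(reps):
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            degs = np.array([d for _, d in g.degree()])
            hist += np.bincount(degs, minlength=n)
        emp = hist / hist.sum()
        assert np.abs(emp - models["random"]).sum() / 2 < 0.02  # total variation

    def test_subsampled_scale_free_invariant_to_parent_size(self):
        """Subsampled preferential-attachment law barely depends on parent size."""
        a = model_degree_distributions(n=50, p=0.04, parent_n=500,
                                       n_parents=30, n_subsamples=20, seed=1)
        b = model_degree_distributions(n=50, p=0.04, parent_n=1000,
                                       n_parents=30, n_subsamples=20, seed=2)
        tv = np.abs(a["scalefree_subsampled"] - b["scalefree_subsampled"]).sum() / 2
        assert tv < 0.05


class TestChi2:
    def test_perfect_match_is_zero(self):
        obs = np.array([0.5, 0.3, 0.2])
        sem = np.array([0.05, 0.05, 0.05])
        assert chi2_compare(obs, sem, obs) == 0.0

    def test_hand_computed_three_bin_case(self):
        obs = np.array([0.5, 0.3, 0.2])
        model = np.array([0.45, 0.35, 0.2])
        sem = np.array([0.05, 0.1, 0.02])
        expected = ((0.05 / 0.05) ** 2 + (0.05 / 0.1) ** 2 + 0.0) / 3
        assert chi2_compare(obs, sem, model) == pytest.approx(expected)

    def test_invariant_to_bin_order(self, rng):
        obs = rng.uniform(0, 1, 8)
        model = rng.uniform(0, 1, 8)
        sem = rng.uniform(0.01, 0.1, 8)
        perm = rng.permutation(8)
        assert chi2_compare(obs, sem, model) == pytest.approx(
            chi2_compare(obs[perm], sem[perm], model[perm])
        )

    def test_zero_dof_rejected(self):
        with pytest.raises(ValueError):
            chi2_compare(np.array([0.5]), np.array([0.0]), np.array([0.5]))


class TestSubsampleMetrics:
    def _demo_net(self, n=12):
        rng = np.random.default_rng(0)
        edges, ratios = [], []
        for i in range(n):
            for j in range(i + 1, n):
                if rng.random() < 0.3:
                    edges.append((i, j))
                    ratios.append(float(rng.uniform(1, 10)))
        return _net(n, edges, ratios=ratios)

    def test_whole_population_single_repeat_equals_direct_computation(self):
        net = self._demo_net()
        spec = SubsampleSpec(n_nodes=12, n_repeats=1, densities=(1.0,),
                             reference_density=1.0, seed=5)
        res = subsample_metrics(net, spec)
        g = to_graph(net)
        assert res.mean["disconnected"][0] == disconnected_count(g)
        assert res.mean["clustering"][0] == pytest.approx(clustering_global(g))
        assert res.mean["efficiency"][0] == pytest.approx(efficiency(g))
        assert res.mean["assortativity"][0] == pytest.approx(assortativity(g))

    def test_seed_determinism(self):
        net = self._demo_net()
        spec = SubsampleSpec(n_nodes=8, n_repeats=10, densities=(0.2, 0.5),
                             reference_density=0.2, seed=5)
        a = subsample_metrics(net, spec)
        b = subsample_metrics(net, spec)
        for m in a.mean:
            assert np.allclose(a.mean[m], b.mean[m], equal_nan=True)
        assert np.allclose(a.degree_distribution, b.degree_distribution)

    def test_empty_edge_set_degenerate_values(self):
        net = _net(10, [])
        spec = SubsampleSpec(n_nodes=5, n_repeats=3, densities=(0.5,),
                             reference_density=0.5, seed=1)
        res = subsample_metrics(net, spec)
        assert res.mean["disconnected"][0] == 5
        assert np.isnan(res.mean["clustering"][0])
        assert res.mean["efficiency"][0] == 0.0
        assert res.undefined["assortativity"][0] == 3

    def test_population_smaller_than_sample_rejected(self):
        with pytest.raises(ValueError):
            subsample_metrics(_net(5, []), SubsampleSpec(n_nodes=10))

    def test_rms_shrinks_toward_full_population(self):
        net = self._demo_net(n=14)
        common = dict(n_repeats=40, densities=(0.3,), reference_density=0.3, seed=2)
        small = subsample_metrics(net, SubsampleSpec(n_nodes=7, **common))
        big = subsample_metrics(net, SubsampleSpec(n_nodes=13, **common))
        assert big.rms["efficiency"][0] <= small.rms["efficiency"][0]


class TestFitDecay:
    def _wired_nets(self, A, lam, C, n_nets=6, n_nodes=300, seed=0):
        from wavecon.synthetic import hexagonal_positions

        nets = []
        rng = np.random.default_rng(seed)
        for _ in range(n_nets):
            pos = hexagonal_positions(n_nodes, rng, scatter_um=5.0)
            positions = {i: (pos[i, 0], pos[i, 1]) for i in range(n_nodes)}
            edges, ratios = [], []
            for i in range(n_nodes):
                for j in range(i + 1, n_nodes):
                    d = np.hypot(*(pos[i] - pos[j]))
                    if rng.random() < A * np.exp(-d / lam) + C:
                        edges.append((i, j))
                        ratios.append(2.0)
            nets.append(_net(n_nodes, edges, ratios=ratios, positions=positions))
        return nets

    def test_recovers_decay_length_within_ci(self):
        nets = self._wired_nets(A=0.05, lam=300.0, C=0.002, seed=304)
        fit = fit_decay(nets)
        lo, hi = fit.ci_lam
        assert lo <= 300.0 <= hi
        assert hi - lo < 300.0  # identifiable, not a degenerate interval

    def test_distance_independent_wiring_flags_wide_interval(self):
        nets = self._wired_nets(A=0.0, lam=300.0, C=0.01, n_nets=3, n_nodes=150)
        fit = fit_decay(nets)
        lo, hi = fit.ci_lam
        assert (hi - lo) > 2 * fit.lam or fit.A < 1e-3

    def test_prediction_stays_in_unit_interval(self):
        nets = self._wired_nets(A=0.05, lam=300.0, C=0.002, n_nets=2, n_nodes=150)
        fit = fit_decay(nets)
        d = np.linspace(0, 2000, 100)
        assert np.all(fit.predict(d) >= 0.0) and np.all(fit.predict(d) <= 1.0)

    def test_too_few_bins_rejected(self):
        positions = {0: (0.0, 0.0), 1: (10.0, 0.0)}
        net = _net(2, [(0, 1)], positions=positions)
        with pytest.raises(ValueError):
            fit_decay([net])
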