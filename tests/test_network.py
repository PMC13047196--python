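import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from casingsoil.io import CountTable
from casingsoil.network import (
    EcoNetwork,
    TooSparseError,
    _cascade,
    _rewire,
    correlation_network,
    detect_modules,
    filter_for_network,
    global_efficiency,
    random_null,
    robustness,
    topology,
    vulnerability,
    zi_pi,
)


def _net(graph):
    net = EcoNetwork(graph=graph)
    net.modules = detect_modules(graph)
    return net


from oracle_graphs import (
    all_partitions as _all_partitions,
    atlas_graphs,
    bf_avg_geodesic as _bf_avg_geodesic,
    bf_clustering as _bf_clustering,
    bf_efficiency as _bf_efficiency,
    bf_modularity as _bf_modularity,
)


class TestFilter:
    def _group_table(self, present):
        counts = np.zeros((18, 4), dtype=int)
        counts[:present, 0] = 5
        counts[:, 1:] = 7
        return CountTable(
            pd.DataFrame(
                counts,
                index=[f"s{i}" for i in range(18)],
                columns=[f"t{j}" for j in range(4)],
            )
        )

    def test_15_of_18_kept(self):
        kept = filter_for_network(self._group_table(15)).taxon_ids
        assert "t0" in kept

    def test_14_of_18_dropped(self):
        kept = filter_for_network(self._group_table(14)).taxon_ids
        assert "t0" not in kept

    def test_full_occupancy_all_kept(self):
        assert len(filter_for_network(self._group_table(18)).taxon_ids) == 4

    def test_too_few_survivors_is_error(self):
        counts = np.zeros((6, 4), dtype=int)
        counts[0, :] = 1  # every taxon occupancy 1/6
        counts[1:, 0] = 1
        with pytest.raises(TooSparseError):
            filter_for_network(
                CountTable(
                    pd.DataFrame(
                        counts,
                        index=[f"s{i}" for i in range(6)],
                        columns=list("wxyz"),
                    )
                )
            )


class TestCorrelationNetwork:
    def _table(self, arr):
        arr = np.asarray(arr)
        return CountTable(
            pd.DataFrame(
                arr,
                index=[f"s{i}" for i in range(arr.shape[0])],
                columns=[f"t{j}" for j in range(arr.shape[1])],
            )
        )

    def test_proportional_taxa_always_linked(self, rng):
        base = rng.integers(10, 50, size=18)
        arr = np.column_stack([base, 2 * base, rng.integers(1, 60, 18)])
        net = correlation_network(self._table(arr), st=0.95)
        assert net.graph.has_edge("t0", "t1")
        assert net.graph["t0"]["t1"]["sign"] == 1

    def test_independent_noise_sparse_at_default_threshold(self, rng):
        arr = rng.integers(1, 100, size=(18, 40))
        net = correlation_network(self._table(arr), st=0.75)
        possible = 40 * 39 / 2
        assert net.n_edges / possible < 0.05

    def test_threshold_monotone_pruning(self, rng):
        arr = rng.integers(1, 100, size=(12, 20))
        arr[:, 1] = arr[:, 0] + rng.integers(0, 6, 12)
        loose = correlation_network(self._table(arr), st=0.5)
        strict = correlation_network(self._table(arr), st=0.9)
        assert set(strict.graph.edges) <= set(loose.graph.edges)

    def test_constant_taxon_dropped_with_warning(self):
        # equal row totals keep t0's RELATIVE abundance exactly constant
        arr = np.empty((10, 3), dtype=int)
        arr[:, 0] = 5
        arr[:, 1] = np.arange(1, 11)
        arr[:, 2] = 20 - np.arange(1, 11)
        with pytest.warns(RuntimeWarning, match="constant"):
            net = correlation_network(self._table(arr), st=0.8)
        assert "t0" not in net.graph.nodes


class TestTopologyOracles:
    def test_triangle(self):
        stats = topology(_net(nx.complete_graph(3)))
        assert stats.avg_geodesic == 1.0
        assert stats.avg_clustering == 1.0
        assert abs(stats.modularity) < 1e-12

    def test_two_triangles_modularity_is_half(self):
        g = nx.Graph([(1, 2), (2, 3), (1, 3), (4, 5), (5, 6), (4, 6)])
        stats = topology(_net(g))
        assert stats.modularity == pytest.approx(0.5)
        # brute force: no partition of the 6 nodes scores higher
        best = max(
            _bf_modularity(g, part) for part in _all_partitions(list(g.nodes))
        )
        assert best == pytest.approx(0.5)

    def test_connectivity_identity_on_atlas(self):
        for g in itertools.islice(atlas_graphs(), 50):
            stats = topology(_net(g))
            assert stats.avg_connectivity == pytest.approx(
                2 * g.number_of_edges() / g.number_of_nodes()
            )

    def test_geodesic_clustering_efficiency_match_brute_force(self):
        count = 0
        for g in atlas_graphs(max_nodes=6):
            net = _net(g)
            stats = topology(net)
            bf_geo = _bf_avg_geodesic(g)
            assert stats.avg_geodesic == pytest.approx(bf_geo)
            assert stats.avg_clustering == pytest.approx(_bf_clustering(g))
            assert global_efficiency(g) == pytest.approx(_bf_efficiency(g))
            count += 1
        assert count > 100  # the atlas holds all graphs up to 6 nodes

    def test_modularity_matches_definition_on_atlas(self):
        for g in itertools.islice(atlas_graphs(), 120):
            net = _net(g)
            partition = {}
            for node, mid in net.modules.items():
                partition.setdefault(mid, []).append(node)
            assert topology(net).modularity == pytest.approx(
                _bf_modularity(g, list(partition.values())), abs=1e-12
            )


class TestRandomNull:
    def test_degree_sequence_preserved(self, rng):
        g = nx.gnm_random_graph(30, 60, seed=2)
        degrees = dict(g.degree())
        for _ in range(5):
            r = _rewire(g, 10 * g.number_of_edges(), rng)
            assert dict(r.degree()) == degrees

    def test_seeded_null_deterministic(self):
        g = nx.gnm_random_graph(20, 40, seed=3)
        net = _net(g)
        a = random_null(net, n_rand=10, seed=5)
        b = random_null(net, n_rand=10, seed=5)
        assert a == b

    def test_modular_toy_graph_exceeds_random_clustering(self):
        g = nx.Graph()
        for offset in (0, 10):
            nodes = range(offset, offset + 8)
            g.add_edges_from(itertools.combinations(nodes, 2))
        g.add_edge(0, 10)
        net = _net(g)
        emp = topology(net).avg_clustering
        null = random_null(net, n_rand=100, seed=1)
        mean, sd = null["avg_clustering"]
        assert emp > mean + 2 * sd

    def test_complete_graph_returns_empirical_with_warning(self):
        net = _net(nx.complete_graph(6))
        with pytest.warns(RuntimeWarning, match="rewired"):
            null = random_null(net, n_rand=10, seed=0)
        assert null["avg_clustering"] == (1.0, 0.0)


class TestRobustness:
    def test_complete_graph_no_secondary_extinction(self):
        net = _net(nx.complete_graph(10))
        assert robustness(net, 0.5, n_rep=50, seed=0) == pytest.approx(0.5)

    def test_star_hub_removal_cascades_fully(self):
        g = nx.star_graph(9)  # hub 0 + 9 leaves
        survivors = _cascade(g, {0, 1, 2, 3, 4})
        assert survivors == 0

    def test_monotone_in_removal_fraction(self):
        g = nx.gnm_random_graph(40, 60, seed=1)
        net = _net(g)
        vals = [
            robustness(net, f, n_rep=200, seed=2)
            for f in (0.2, 0.4, 0.6, 0.8)
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_bounded_by_one_minus_f(self):
        g = nx.gnm_random_graph(30, 45, seed=4)
        net = _net(g)
        val = robustness(net, 0.5, n_rep=100, seed=0)
        assert 0.0 <= val <= 0.5 + 1e-12


class TestVulnerability:
    def test_complete_graph_zero(self):
        assert vulnerability(_net(nx.complete_graph(6))) == pytest.approx(0.0)

    def test_path_graph_hand_case(self):
        # E = (1+1+0.5)/3 = 0.8333; removing the middle node -> E = 0
        g = nx.path_graph(["A", "B", "C"])
        assert global_efficiency(g) == pytest.approx(5 / 6)
        assert vulnerability(_net(g)) == pytest.approx(1.0)

    def test_nonnegative_on_random_graphs(self, rng):
        for seed in range(3):
            g = nx.connected_watts_strogatz_graph(15, 4, 0.2, seed=seed)
            assert vulnerability(_net(g)) >= 0

    def test_too_small_rejected(self):
        with pytest.raises(ValueError):
            vulnerability(_net(nx.path_graph(2)))


class TestZiPi:
    def test_all_links_internal_gives_zero_pi(self):
        g = nx.complete_graph(4)
        net = _net(g)
        roles = {r.taxon: r for r in zi_pi(net)}
        assert all(r.pi == 0.0 for r in roles.values())

    def test_even_split_four_links_gives_half(self):
        g = nx.Graph(
            [("x", "a1"), ("x", "a2"), ("x", "b1"), ("x", "b2"),
             ("a1", "a2"), ("b1", "b2")]
        )
        net = EcoNetwork(graph=g)
        net.modules = {"x": 0, "a1": 0, "a2": 0, "b1": 1, "b2": 1}
        roles = {r.taxon: r for r in zi_pi(net)}
        assert roles["x"].pi == pytest.approx(1 - 2 * 0.5**2)

    def test_mean_degree_node_has_zero_zi(self):
        g = nx.complete_graph(5)  # all within-degrees equal -> sd 0 -> zi 0
        roles = zi_pi(_net(g))
        assert all(r.zi == 0.0 for r in roles)

    def test_pi_in_unit_interval_and_roles_consistent(self, rng):
        g = nx.gnm_random_graph(40, 90, seed=7)
        net = _net(g)
        for role in zi_pi(net):
            assert 0.0 <= role.pi <= 1.0
            expected = (
                "network_hub" if role.zi > 2.5 and role.pi > 0.62
                else "module_hub" if role.zi > 2.5
                else "connector" if role.pi > 0.62
                else "peripheral"
            )
            assert role.role == expected
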