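import itertools

import networkx as nx
import numpy as np
import pytest

from spikelink import (clustering_coefficient, graph_from_matrix, path_length,
                       random_equivalents, rich_club_curve, small_world_index)
from spikelink.topology import select_subgrid


def brute_force_clustering(g):
    out = {}
    for x in g.nodes:
        nbrs = list(g.neighbors(x))
        if len(nbrs) < 2:
            out[x] = 0.0
            continue
        u = sum(1 for a, b in itertools.combinations(nbrs, 2)
                if g.has_edge(a, b))
        out[x] = 2.0 * u / (len(nbrs) * (len(nbrs) - 1))
    return out


def brute_force_path_length(g):
    total, count = 0, 0
    nodes = list(g.nodes)
    for a, b in itertools.combinations(nodes, 2):
        try:
            d = nx.shortest_path_length(g, a, b)
        except nx.NetworkXNoPath:
            continue
        total += d
        count += 1
    return total / count if count else None


class TestClusteringCoefficient:
    def test_triangle(self):
        per_node, mean = clustering_coefficient(nx.complete_graph(3))
        assert all(v == 1.0 for v in per_node.values())
        assert mean == 1.0

    def test_path_graph_all_zero(self):
        _, mean = clustering_coefficient(nx.path_graph(3))
        assert mean == 0.0

    def test_hand_enumerated_graph(self):
        g = nx.Graph([("a", "b"), ("b", "c"), ("c", "a"), ("c", "d")])
        per_node, mean = clustering_coefficient(g)
        assert per_node["a"] == 1.0 and per_node["b"] == 1.0
        assert per_node["c"] == pytest.approx(1 / 3)
        assert per_node["d"] == 0.0
        assert mean == pytest.approx(7 / 12)


class TestPathLength:
    def test_complete_graph(self):
        pl, frac = path_length(nx.complete_graph(6))
        assert pl == 1.0 and frac == 0.0

    def test_path_of_three(self):
        pl, _ = path_length(nx.path_graph(3))
        assert pl == pytest.approx(4 / 3)

    def test_ring_of_four(self):
        pl, _ = path_length(nx.cycle_graph(4))
        assert pl == pytest.approx(4 / 3)

    def test_disconnected_pairs_excluded_and_reported(self):
        g = nx.Graph([(0, 1), (2, 3)])
        pl, frac = path_length(g)
        assert pl == 1.0
        assert frac == pytest.approx(4 / 6)

    def test_no_connected_pairs_rejected(self):
        with pytest.raises(ValueError):
            path_length(nx.empty_graph(4))


class TestOracleAgreement:
    def test_clustering_and_path_length_match_brute_force(self, rng):
        for _ in range(40):
            n = int(rng.integers(4, 50))
            p = rng.uniform(0.05, 0.5)
            g = nx.gnp_random_graph(n, p, seed=int(rng.integers(2**31)))
            per_node, mean = clustering_coefficient(g)
            expected = brute_force_clustering(g)
            for node in g.nodes:
                assert per_node[node] == pytest.approx(expected[node])
            bf = brute_force_path_length(g)
            if bf is None:
                with pytest.raises(ValueError):
                    path_length(g)
            else:
                assert path_length(g)[0] == pytest.approx(bf)


class TestRandomEquivalents:
    def test_degree_sequence_preserved(self, rng):
        g = nx.gnp_random_graph(30, 0.2, seed=1)
        from spikelink.topology import _surrogate
        rng2 = np.random.default_rng(0)
        for _ in range(5):
            s = _surrogate(g, "degree_preserving", rng2)
            assert sorted(dict(s.degree()).values()) == \
                sorted(dict(g.degree()).values())

    def test_er_graph_self_similar(self):
        g = nx.gnp_random_graph(100, 0.1, seed=2)
        _, c_net = clustering_coefficient(g)
        l_net, _ = path_length(g)
        c_rnd, l_rnd = random_equivalents(g, n_surrogates=20, seed=3)
        assert c_rnd == pytest.approx(c_net, rel=0.5)
        assert l_rnd == pytest.approx(l_net, rel=0.2)

    def test_sparse_graph_falls_back_with_warning(self):
        g = nx.Graph([(0, 1)])
        with pytest.warns(UserWarning):
            random_equivalents(g, n_surrogates=2, seed=0)


class TestSmallWorldIndex:
    def test_er_graph_swi_near_one(self):
        g = nx.gnp_random_graph(200, 0.08, seed=4)
        report = small_world_index(g, n_surrogates=20, seed=5)
        assert abs(report.swi - 1.0) < 0.1

    def test_watts_strogatz_swi_much_greater_than_one(self):
        g = nx.watts_strogatz_graph(500, 10, 0.05, seed=6)
        report = small_world_index(g, n_surrogates=10, seed=7)
        assert report.c_net > 3 * report.c_rnd
        assert report.swi > 3.0

    def test_isomorphism_invariance(self):
        g = nx.watts_strogatz_graph(100, 6, 0.1, seed=8)
        relabeled = nx.relabel_nodes(g, {i: f"x{i}" for i in g.nodes})
        a = small_world_index(g, n_surrogates=10, seed=9)
        b = small_world_index(relabeled, n_surrogates=10, seed=9)
        assert a.c_net == pytest.approx(b.c_net)
        assert a.l_net == pytest.approx(b.l_net)
        assert a.swi == pytest.approx(b.swi, rel=0.2)


class TestRichClub:
    def test_complete_graph_density_one(self):
        res = rich_club_curve(nx.complete_graph(5), n_surrogates=5, seed=0)
        assert res.k[0] == 1
        assert res.raw[0] == pytest.approx(1.0)

    def test_star_graph_low_k_undefined(self):
        res = rich_club_curve(nx.star_graph(5), n_surrogates=5, seed=0)
        assert 1 not in res.k.tolist()

    def test_two_cliques_bridge_matches_subgraph_density_oracle(self):
        g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
        g.add_edge(0, 4)
        res = rich_club_curve(g, n_surrogates=5, seed=1)
        degrees = dict(g.degree())
        nodes = [v for v, d in degrees.items() if d > 3]
        sub = g.subgraph(nodes)
        expected = 2 * sub.number_of_edges() / (len(nodes) * (len(nodes) - 1))
        assert res.raw[res.k.tolist().index(3)] == pytest.approx(expected)

    def test_raw_curve_matches_networkx(self):
        g = nx.gnp_random_graph(60, 0.15, seed=10)
        res = rich_club_curve(g, n_surrogates=2, seed=11)
        nx_rc = nx.rich_club_coefficient(g, normalized=False)
        for k, raw in zip(res.k, res.raw):
            assert raw == pytest.approx(nx_rc[k])

    def test_er_graph_normalized_near_one(self):
        g = nx.gnp_random_graph(100, 0.2, seed=12)
        res = rich_club_curve(g, n_surrogates=20, seed=13)
        defined = np.isfinite(res.normalized)
        low_k = res.k[defined] <= np.percentile(res.k[defined], 80)
        assert np.all(np.abs(res.normalized[defined][low_k] - 1.0) < 0.5)


class TestDecimation:
    def test_subgrid_selection_counts_and_uniformity(self):
        from spikelink import ElectrodeLayout
        layout = ElectrodeLayout.from_grid(64, 64, 42.0)
        chosen = select_subgrid(layout, 60)
        assert len(chosen) == 60
        sub = layout.subset(chosen)
        # uniform stride: nearest-neighbour pitch well above the native 42 um
        assert np.diff(np.unique(sub.x_um)).min() >= 42.0 * 4

    def test_requesting_too_many_channels_rejected(self):
        from spikelink import ElectrodeLayout
        layout = ElectrodeLayout.from_grid(4, 4, 100.0)
        with pytest.raises(ValueError):
            select_subgrid(layout, 20)

    def test_full_set_is_identity_subset(self):
        from spikelink import ElectrodeLayout
        layout = ElectrodeLayout.from_grid(6, 6, 100.0)
        chosen = select_subgrid(layout, 36)
        assert sorted(chosen) == sorted(layout.channel_ids)


class TestDecimationPipeline:
    def test_full_set_reproduces_undecimated_metrics(self, rng):
        from conftest import poisson_train
        from spikelink import (ElectrodeLayout, NcchConnectivity,
                               PruningParams, SpikeTrainSet, decimation_study)

        layout = ElectrodeLayout.from_grid(5, 5, 200.0)
        spikes = {ch: poisson_train(10.0, 30.0, rng)
                  for ch in layout.channel_ids}
        s = SpikeTrainSet(spikes, 10_000.0, 30.0)
        table = decimation_study(s, layout, [25, 9], n_surrogates=5, seed=0)
        assert table.n_electrodes.tolist() == [25, 9]
        full = table.iloc[0]
        # direct pipeline on the identical channel set, same surrogate seed
        res = NcchConnectivity(s, layout=layout).fit()
        res = res.spatiotemporal_filter(PruningParams(), layout)
        res = res.hard_threshold(PruningParams())
        g = graph_from_matrix(res.fcm, "excitatory")
        if np.isfinite(full.swi):
            direct = small_world_index(g, n_surrogates=5, seed=0)
            assert full.swi == pytest.approx(direct.swi)
            assert full.c_net == pytest.approx(direct.c_net)

    def test_counts_must_be_descending(self):
        from spikelink import ElectrodeLayout, decimation_study
        layout = ElectrodeLayout.from_grid(4, 4, 100.0)
        with pytest.raises(ValueError):
            decimation_study(None, layout, [4, 16])
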