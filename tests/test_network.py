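"""Network topology: construction, centralities vs brute-force oracles, hubs."""

import numpy as np
import pytest

from mirnet_pd.network import (
    betweenness_centrality,
    build_network,
    centrality_table,
    closeness_centrality,
    degree_centrality,
    network_summary,
    rank_hubs,
    write_graphml,
    write_sif,
)
from mirnet_pd.targets import Interaction

from oracles import (
    net_from_edges,
    oracle_betweenness,
    oracle_closeness,
    oracle_degree,
    random_bipartite,
)

STAR = [("m1", "g1"), ("m1", "g2"), ("m1", "g3")]  # K(1,3), center m1
PATH = [("m1", "g1"), ("m2", "g1")]  # path m1-g1-m2
CYCLE4 = [("m1", "g1"), ("m1", "g2"), ("m2", "g1"), ("m2", "g2")]


class TestConstruction:
    def test_minimal(self):
        net = build_network({"m1"}, [Interaction("m1", "G1", "strong")], {"G1"})
        assert net.n_nodes == 2 and net.n_edges == 1

    def test_shared_target(self):
        inter = [Interaction("m1", "G1", "strong"), Interaction("m2", "G1", "strong")]
        net = build_network({"m1", "m2"}, inter, {"G1"})
        assert net.n_nodes == 3 and net.n_edges == 2

    def test_nodes_outside_universe_or_set_dropped(self):
        inter = [
            Interaction("m1", "G1", "strong"),
            Interaction("m1", "G2", "strong"),  # G2 not in universe
            Interaction("m3", "G1", "strong"),  # m3 not in the miRNA set
        ]
        net = build_network({"m1"}, inter, {"G1"})
        assert set(net.nodes) == {"m1", "G1"}

    def test_no_isolated_nodes(self):
        net = build_network({"m1", "m2"}, [Interaction("m1", "G1", "strong")], {"G1"})
        assert "m2" not in net.kind

    def test_bipartiteness_enforced(self):
        net = net_from_edges([("m1", "g1")])
        with pytest.raises(ValueError):
            net.add_edge("g1", "m1")  # would flip the kinds

    def test_self_loop_rejected(self):
        net = net_from_edges([("m1", "g1")])
        with pytest.raises(ValueError):
            net.add_edge("x", "x")

    def test_duplicate_edges_collapse(self):
        net = net_from_edges([("m1", "g1"), ("m1", "g1")])
        assert net.n_edges == 1

    def test_generator_bookkeeping(self):
        from mirnet_pd.simulate import simulate_interactions

        table, truth = simulate_interactions(20, 50, density=0.1, seed=7)
        mirnas = {i.mirna_id for i in table}
        genes = {i.gene for i in table}
        net = build_network(mirnas, table, genes)
        strong_or_weak = {(i.mirna_id, i.gene) for i in table}
        assert net.n_edges == len(strong_or_weak) == truth.n_edges


class TestDegree:
    def test_star(self):
        dc = degree_centrality(net_from_edges(STAR))
        assert dc == {"m1": 3, "g1": 1, "g2": 1, "g3": 1}

    def test_path_midpoint(self):
        assert degree_centrality(net_from_edges(PATH))["g1"] == 2

    def test_sum_equals_twice_edges_random(self):
        rng = np.random.default_rng(11)
        for _ in range(200):
            net = random_bipartite(rng)
            dc = degree_centrality(net)
            assert dc == oracle_degree(net)
            assert sum(dc.values()) == 2 * net.n_edges


class TestBetweenness:
    def test_star_center(self):
        bc = betweenness_centrality(net_from_edges(STAR))
        assert bc["m1"] == 3.0  # three leaf pairs route through the center
        assert bc["g1"] == bc["g2"] == bc["g3"] == 0.0

    def test_four_cycle_split_credit(self):
        bc = betweenness_centrality(net_from_edges(CYCLE4))
        # opposite corners have two shortest paths; each node mediates one pair
        assert all(abs(v - 0.5) < 1e-12 for v in bc.values())

    def test_path_endpoints_excluded(self):
        bc = betweenness_centrality(net_from_edges(PATH))
        assert bc == {"m1": 0.0, "g1": 1.0, "m2": 0.0}

    def test_matches_path_enumeration_oracle(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            net = random_bipartite(rng, connected=True)
            bc = betweenness_centrality(net)
            expected = oracle_betweenness(net)
            for v in net.nodes:
                assert bc[v] == pytest.approx(expected[v], abs=1e-9)

    def test_disconnected_graph_matches_oracle(self):
        net = net_from_edges([("m1", "g1"), ("m2", "g2"), ("m2", "g3")])
        assert betweenness_centrality(net) == oracle_betweenness(net)

    def test_matches_networkx_on_random_graphs(self):
        nx = pytest.importorskip("networkx")
        rng = np.random.default_rng(5)
        for _ in range(50):
            net = random_bipartite(rng)
            g = nx.Graph(net.edges)
            g.add_nodes_from(net.nodes)
            expected = nx.betweenness_centrality(g, normalized=False)
            bc = betweenness_centrality(net)
            for v in net.nodes:
                assert bc[v] == pytest.approx(expected[v], abs=1e-9)

    def test_tree_identity_sum_of_path_interiors(self):
        # on a tree, total betweenness equals sum over pairs of (d(u,v) - 1):
        # every interior vertex of the unique path counts exactly once
        from oracles import bfs_dist

        rng = np.random.default_rng(9)
        for _ in range(50):
            # random bipartite tree: each new node attaches to one earlier
            # node of the opposite kind
            n = int(rng.integers(2, 11))
            kinds = ["mirna"]
            names = ["m0"]
            edges = []
            for i in range(1, n):
                j = int(rng.integers(i))
                kind = "gene" if kinds[j] == "mirna" else "mirna"
                name = ("g" if kind == "gene" else "m") + str(i)
                kinds.append(kind)
                names.append(name)
                pair = (names[j], name) if kind == "gene" else (name, names[j])
                edges.append(pair)
            net = net_from_edges(edges)
            assert net.n_edges == n - 1
            total = sum(betweenness_centrality(net).values())
            nodes = net.nodes
            pair_sum = 0.0
            for i, s in enumerate(nodes):
                dist = bfs_dist(net, s)
                for t in nodes[i + 1 :]:
                    pair_sum += dist[t] - 1
            assert total == pytest.approx(pair_sum, abs=1e-9)


class TestCloseness:
    def test_star(self):
        cc = closeness_centrality(net_from_edges(STAR))
        assert cc["m1"] == 1.0
        assert cc["g1"] == pytest.approx(3 / 5)

    def test_path(self):
        cc = closeness_centrality(net_from_edges(PATH))
        assert cc["g1"] == 1.0
        assert cc["m1"] == pytest.approx(2 / 3)

    def test_matches_bfs_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            net = random_bipartite(rng, connected=True)
            cc = closeness_centrality(net)
            expected = oracle_closeness(net)
            for v in net.nodes:
                assert cc[v] == pytest.approx(expected[v], abs=1e-12)
                assert cc[v] <= 1.0 + 1e-12

    def test_disconnected_whole_network_normalization(self):
        # two components of 2; distance sum within component is 1,
        # numerator is N-1 = 3 over the whole network
        net = net_from_edges([("m1", "g1"), ("m2", "g2")])
        cc = closeness_centrality(net)
        assert all(v == pytest.approx(3.0) for v in cc.values())
        within = closeness_centrality(net, within_component_norm=True)
        assert all(v == pytest.approx(1.0) for v in within.values())

    def test_published_convention_pattern(self):
        # in a connected 54-node network, a node at distance-sum 70 must have
        # closeness 53/70 ~ 0.7571428 under the (N-1)/sum convention
        edges = [("HUBG", f"m{i}") for i in range(36)]
        edges = [(m, g) for g, m in edges]  # mirna first
        edges += [("m0", f"g{j}") for j in range(17)]
        net = net_from_edges(edges)
        assert net.n_nodes == 54
        cc = closeness_centrality(net)
        assert cc["HUBG"] == pytest.approx(53 / 70)
        assert abs(cc["HUBG"] - 0.7571428) < 1e-6


class TestHubsAndSummary:
    def test_star_top1(self):
        table = centrality_table(net_from_edges(STAR))
        hubs = rank_hubs(table, "dc", 1)
        assert hubs.ranked[0] == ("m1", 3.0)

    def test_k_exceeding_n_returns_all_nonincreasing(self):
        table = centrality_table(net_from_edges(CYCLE4))
        hubs = rank_hubs(table, "dc", 100)
        values = [v for _n, v in hubs.ranked]
        assert len(values) == 4 and values == sorted(values, reverse=True)

    def test_tie_break_genes_first_then_lexicographic(self):
        table = centrality_table(net_from_edges(CYCLE4))  # all degree 2
        ranked = [n for n, _v in rank_hubs(table, "dc", 4).ranked]
        assert ranked == ["g1", "g2", "m1", "m2"]

    def test_kind_filter_genes_only(self):
        table = centrality_table(net_from_edges(STAR))
        hubs = rank_hubs(table, "dc", 2, kind="gene")
        assert all(n.startswith("g") for n, _v in hubs.ranked)

    def test_planted_hub_ranked_first(self):
        from mirnet_pd.simulate import simulate_interactions

        table, truth = simulate_interactions(20, 50, 0.1, hub_boost=10.0, seed=7)
        strong = [i for i in table if i.evidence == "strong"]
        net = build_network(
            {i.mirna_id for i in strong}, strong, {i.gene for i in strong}
        )
        hubs = rank_hubs(centrality_table(net), "dc", 1)
        assert hubs.ranked[0][0] == truth.planted_hub_gene

    def test_summary_star(self):
        s = network_summary(net_from_edges(STAR))
        assert (s.n_nodes, s.n_edges, s.n_components, s.n_mirna, s.n_gene) == (
            4, 3, 1, 1, 3,
        )

    def test_summary_empty(self):
        s = network_summary(build_network(set(), [], set()))
        assert (s.n_nodes, s.n_edges, s.n_components, s.n_mirna, s.n_gene) == (
            0, 0, 0, 0, 0,
        )

    def test_summary_components(self):
        s = network_summary(net_from_edges([("m1", "g1"), ("m2", "g2")]))
        assert s.n_components == 2


class TestExport:
    def test_sif_roundtrip_edges(self, tmp_path):
        net = net_from_edges(STAR)
        p = tmp_path / "n.sif"
        write_sif(net, p)
        lines = p.read_text().strip().split("\n")
        assert len(lines) == 3 and all(l.split("\t")[1] == "targets" for l in lines)

    def test_graphml_parses_and_keeps_kinds(self, tmp_path):
        import xml.etree.ElementTree as ET

        net = net_from_edges(STAR)
        p = tmp_path / "n.graphml"
        write_graphml(net, p)
        root = ET.parse(p).getroot()
        ns = {"g": "http://graphml.graphdrawing.org/xmlns"}
        nodes = root.findall(".//g:node", ns)
        kinds = {n.get("id"): n.find("g:data", ns).text for n in nodes}
        assert kinds == {"m1": "mirna", "g1": "gene", "g2": "gene", "g3": "gene"}
        assert len(root.findall(".//g:edge", ns)) == 3
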