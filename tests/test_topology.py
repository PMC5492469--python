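"""Topology metrics, fast-greedy modularity vs brute force, nulls, Zi-Pi roles."""

import networkx as nx
import numpy as np
import pytest

import bloomnet as bn
from bloomnet.rmt import EcologicalNetwork
from bloomnet.synthetic import BACKGROUND_MODULE
from tests.conftest import make_network


def set_partitions(items):
    """All partitions of a list (restricted-growth enumeration)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i, block in enumerate(smaller):
            yield smaller[:i] + [[first] + block] + smaller[i + 1:]
        yield [[first]] + smaller


def brute_force_max_q(net: EcologicalNetwork) -> float:
    """Exhaustive maximum modularity over all node partitions (oracle)."""
    nodes = sorted(net.graph.nodes)
    best = -1.0
    for partition in set_partitions(nodes):
        mapping = {n: i for i, block in enumerate(partition) for n in block}
        best = max(best, bn.modularity(net, mapping))
    return best


class TestTopologySummary:
    @pytest.mark.parametrize("n,l,expected", [(222, 536, 4.829), (480, 886, 3.692)])
    def test_average_connectivity_identity(self, n, l, expected):
        g = nx.gnm_random_graph(n, l, seed=0)
        for u, v in g.edges:
            g.edges[u, v].update(correlation=1.0, sign="positive")
        summary = bn.topology_summary(EcologicalNetwork(g))
        assert summary.avg_k == pytest.approx(expected, abs=1e-3)

    def test_complete_graph_k5(self):
        g = nx.complete_graph(5)
        nx.set_edge_attributes(g, 1.0, "correlation")
        nx.set_edge_attributes(g, "positive", "sign")
        s = bn.topology_summary(EcologicalNetwork(g))
        assert s.avg_k == 4 and s.gd == 1 and s.avg_cc == 1

    def test_path_graph_hand_enumeration(self):
        s = bn.topology_summary(make_network([("a", "b"), ("b", "c")]))
        assert s.gd == pytest.approx((1 + 1 + 2) / 3)
        assert s.avg_cc == 0.0

    def test_gd_skips_disconnected_pairs(self, two_triangles_apart):
        s = bn.topology_summary(two_triangles_apart)
        assert s.gd == 1.0  # all reachable pairs are adjacent

    def test_empty_network_raises(self):
        with pytest.raises(ValueError, match="empty"):
            bn.topology_summary(EcologicalNetwork(nx.Graph()))


class TestModularity:
    def test_single_community_is_zero(self, two_triangles_joined):
        part = {n: 1 for n in two_triangles_joined.graph.nodes}
        assert bn.modularity(two_triangles_joined, part) == pytest.approx(0.0)

    def test_k2_singletons(self):
        net = make_network([("a", "b")])
        assert bn.modularity(net, {"a": 1, "b": 2}) == pytest.approx(-0.5)

    def test_two_components_natural_partition(self, two_triangles_apart):
        part = {n: (1 if n in "abc" else 2) for n in two_triangles_apart.graph.nodes}
        assert bn.modularity(two_triangles_apart, part) == pytest.approx(0.5)

    def test_missing_node_raises(self, two_triangles_apart):
        with pytest.raises(ValueError, match="missing"):
            bn.modularity(two_triangles_apart, {"a": 1})

    def test_agrees_with_networkx(self):
        rng = np.random.default_rng(3)
        g = nx.gnm_random_graph(20, 40, seed=3)
        net = EcologicalNetwork(g)
        part, q = bn.fast_greedy_partition(net)
        communities = {}
        for node, m in part.items():
            communities.setdefault(m, set()).add(node)
        assert q == pytest.approx(
            nx.community.modularity(g, list(communities.values())))


class TestFastGreedy:
    def test_two_triangles_joined(self, two_triangles_joined):
        part, q = bn.fast_greedy_partition(two_triangles_joined)
        assert q == pytest.approx(0.357, abs=1e-3)
        assert len(set(part.values())) == 2
        assert part["a"] == part["b"] == part["c"]

    def test_two_triangles_apart(self, two_triangles_apart):
        _, q = bn.fast_greedy_partition(two_triangles_apart)
        assert q == pytest.approx(0.5)

    def test_single_edge(self):
        part, q = bn.fast_greedy_partition(make_network([("a", "b")]))
        assert q == 0.0
        assert len(set(part.values())) == 1

    def test_returned_q_equals_modularity_of_partition(self):
        g = nx.gnm_random_graph(30, 60, seed=5)
        net = EcologicalNetwork(g)
        part, q = bn.fast_greedy_partition(net)
        assert q == bn.modularity(net, part)

    def test_deterministic(self):
        g = nx.gnm_random_graph(25, 50, seed=9)
        net = EcologicalNetwork(g)
        assert bn.fast_greedy_partition(net) == bn.fast_greedy_partition(net)

    @pytest.mark.parametrize("seed", range(10))
    def test_near_optimal_on_small_graphs(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 8))
        g = nx.gnp_random_graph(n, 0.5, seed=seed)
        if g.number_of_edges() == 0 or not nx.is_connected(g):
            g = nx.path_graph(n)
        net = EcologicalNetwork(g)
        _, q = bn.fast_greedy_partition(net)
        assert q >= brute_force_max_q(net) - 0.05


class TestRandomize:
    def test_degree_sequence_preserved(self, planted_analysis):
        net = planted_analysis.network
        null = bn.randomize_network(net, seed=0)
        assert dict(null.graph.degree) == dict(net.graph.degree)
        assert null.n_links == net.n_links

    def test_star_graph_unchanged(self):
        star = make_network([("hub", f"leaf{i}") for i in range(5)])
        null = bn.randomize_network(star, seed=1)
        assert set(map(frozenset, null.graph.edges)) == \
               set(map(frozenset, star.graph.edges))

    def test_deterministic_under_seed(self, two_triangles_joined):
        a = bn.randomize_network(two_triangles_joined, seed=7)
        b = bn.randomize_network(two_triangles_joined, seed=7)
        assert set(a.graph.edges) == set(b.graph.edges)

    def test_actually_rewires(self, planted_analysis):
        net = planted_analysis.network
        null = bn.randomize_network(net, seed=0)
        assert set(map(frozenset, null.graph.edges)) != \
               set(map(frozenset, net.graph.edges))


class TestNullDistribution:
    def test_single_replicate_sd_zero(self, two_triangles_joined):
        summary = bn.null_distribution(two_triangles_joined, 1, seed=0)
        assert summary.modularity_sd == 0.0
        assert summary.n_randomizations == 1

    def test_star_graph_degenerate(self):
        star = make_network([("hub", f"leaf{i}") for i in range(5)])
        summary = bn.null_distribution(star, 5, seed=0)
        assert summary.modularity_sd == 0.0
        assert summary.gd_sd == 0.0
        assert summary.avg_cc_sd == 0.0

    def test_zero_replicates_rejected(self, two_triangles_joined):
        with pytest.raises(ValueError):
            bn.null_distribution(two_triangles_joined, 0, seed=0)


class TestZiPi:
    def test_all_links_internal_gives_pi_zero(self, two_triangles_apart):
        part = {n: (1 if n in "abc" else 2) for n in two_triangles_apart.graph.nodes}
        records = bn.zi_pi(two_triangles_apart, part)
        assert all(r.pi == 0.0 for r in records)

    def test_even_split_gives_pi_half(self):
        net = make_network([("x", "a"), ("x", "b")])
        records = {r.otu_id: r for r in bn.zi_pi(net, {"x": 1, "a": 1, "b": 2})}
        assert records["x"].pi == pytest.approx(0.5)

    def test_equal_within_degree_gives_zi_zero(self, two_triangles_apart):
        part = {n: (1 if n in "abc" else 2) for n in two_triangles_apart.graph.nodes}
        assert all(r.zi == 0.0 for r in bn.zi_pi(two_triangles_apart, part))

    def test_pi_bounded(self, planted_analysis):
        records = bn.zi_pi(planted_analysis.network, planted_analysis.partition)
        assert all(0.0 <= r.pi <= 1.0 for r in records)

    def test_roles_invariant_under_relabeling(self, two_triangles_joined):
        part = {n: (1 if n in "abc" else 2) for n in two_triangles_joined.graph.nodes}
        base = bn.classify_roles(bn.zi_pi(two_triangles_joined, part))
        relabeled = make_network([(u.upper(), v.upper())
                                  for u, v in two_triangles_joined.graph.edges])
        part_up = {n.upper(): m for n, m in part.items()}
        upper = bn.classify_roles(bn.zi_pi(relabeled, part_up))
        assert {r.otu_id.upper(): (r.zi, r.pi, r.role) for r in base} == \
               {r.otu_id: (r.zi, r.pi, r.role) for r in upper}


class TestClassifyRoles:
    @pytest.mark.parametrize("zi,pi,role", [
        (3.0, 0.10, "module hub"),
        (1.0, 0.70, "connector"),
        (2.6, 0.63, "network hub"),
        (0.0, 0.00, "peripheral"),
        (2.5, 0.62, "peripheral"),   # thresholds are strict inequalities
        (2.51, 0.62, "module hub"),
        (2.5, 0.621, "connector"),
    ])
    def test_threshold_taxonomy(self, zi, pi, role):
        rec = bn.NodeRoleRecord("x", 1, 3, 2, zi, pi)
        assert bn.classify_roles([rec])[0].role == role


class TestEgo:
    def test_tally(self):
        net = make_network([("f", "a", 0.95), ("f", "b", 0.91), ("f", "c", 0.92),
                            ("f", "d", -0.93), ("a", "b", 0.99)])
        ego = bn.ego_subnetwork(net, "f")
        assert (ego.n_positive, ego.n_negative) == (3, 1)
        assert [n for n, *_ in ego.neighbors] == ["a", "b", "c", "d"]

    def test_symmetry(self, two_triangles_joined):
        g = two_triangles_joined
        for u, v in g.graph.edges:
            assert u in [n for n, *_ in bn.ego_subnetwork(g, v).neighbors]
            assert v in [n for n, *_ in bn.ego_subnetwork(g, u).neighbors]

    def test_absent_focal_raises(self, two_triangles_joined):
        with pytest.raises(ValueError, match="not in network"):
            bn.ego_subnetwork(two_triangles_joined, "zz")


class TestModuleEdgeAccounting:
    def test_within_module_edges_bounded_by_total(self, planted_analysis):
        net = planted_analysis.network
        part = planted_analysis.partition
        within = sum(1 for u, v in net.graph.edges if part[u] == part[v])
        assert within <= net.n_links
        between = net.n_links - within
        assert (within == net.n_links) == (between == 0)
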