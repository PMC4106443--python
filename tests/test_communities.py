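"""Greedy modularity: formula checks, exhaustive oracle, determinism."""

import itertools

import networkx as nx
import numpy as np
import pytest

from crenet.coexpression import Network, correlation_network, intersect_networks, z_transform
from crenet.communities import (
    Partition,
    greedy_modularity,
    modularity,
    partition_similarity,
    regulatory_modules,
)


def net_from_edges(nodes, edges):
    idx = {g: i for i, g in enumerate(nodes)}
    adj = np.zeros((len(nodes), len(nodes)), bool)
    for a, b in edges:
        adj[idx[a], idx[b]] = adj[idx[b], idx[a]] = True
    return Network(list(nodes), adj, 0.5)


def set_partitions(items):
    """All partitions of a small item list (exhaustive oracle)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for smaller in set_partitions(rest):
        for i in range(len(smaller)):
            yield smaller[:i] + [smaller[i] + [first]] + smaller[i + 1 :]
        yield [[first]] + smaller


def two_cliques_with_bridge():
    left = [f"a{i}" for i in range(4)]
    right = [f"b{i}" for i in range(4)]
    edges = list(itertools.combinations(left, 2)) + list(itertools.combinations(right, 2))
    edges.append((left[0], right[0]))
    return net_from_edges(left + right, edges), left, right


class TestModularity:
    def test_single_community_scores_zero(self):
        net, left, right = two_cliques_with_bridge()
        part = {g: 0 for g in net.nodes}
        assert modularity(net, part) == pytest.approx(0.0)

    def test_two_disjoint_triangles_score_half(self):
        net = net_from_edges(
            list("abcdef"),
            [("a", "b"), ("b", "c"), ("a", "c"), ("d", "e"), ("e", "f"), ("d", "f")],
        )
        part = {g: (0 if g in "abc" else 1) for g in net.nodes}
        assert modularity(net, part) == pytest.approx(0.5)

    def test_matches_networkx_formula(self, rng):
        nodes = [f"g{i}" for i in range(15)]
        adj = np.triu(rng.random((15, 15)) < 0.3, 1)
        net = Network(nodes, adj | adj.T, 0.5)
        part = {g: int(rng.integers(0, 3)) for g in nodes}
        if net.n_edges == 0:
            pytest.skip("degenerate draw")
        communities = [
            {g for g in nodes if part[g] == c} for c in sorted(set(part.values()))
        ]
        communities = [c for c in communities if c]
        expected = nx.community.modularity(net.to_networkx(), communities)
        assert modularity(net, part) == pytest.approx(expected)

    def test_missing_node_rejected(self):
        net, *_ = two_cliques_with_bridge()
        with pytest.raises(ValueError):
            modularity(net, {net.nodes[0]: 0})


class TestGreedyModularity:
    def test_recovers_cliques_and_matches_exhaustive_maximum(self):
        net, left, right = two_cliques_with_bridge()
        part = greedy_modularity(net)
        comms = {frozenset(m) for m in part.communities().values()}
        assert comms == {frozenset(left), frozenset(right)}
        best_q = max(
            modularity(net, {g: i for i, block in enumerate(p) for g in block})
            for p in set_partitions(net.nodes)
        )
        assert part.q == pytest.approx(best_q)

    def test_noiseless_planted_partition_recovered(self, planted_network):
        ts, truth = planted_network
        nets = [correlation_network(z_transform(m), 0.6) for m in ts.values()]
        part = greedy_modularity(intersect_networks(nets))
        assert partition_similarity(part.membership, dict(truth)) == pytest.approx(1.0)

    def test_returned_q_non_negative_when_positive_merge_exists(self, rng):
        nodes = [f"g{i}" for i in range(12)]
        adj = np.triu(rng.random((12, 12)) < 0.4, 1)
        net = Network(nodes, adj | adj.T, 0.5)
        if net.n_edges == 0:
            pytest.skip("degenerate draw")
        part = greedy_modularity(net)
        assert part.q >= 0.0
        assert part.q == pytest.approx(modularity(net, part.membership))

    def test_merge_history_consistent_with_recomputation(self):
        net, *_ = two_cliques_with_bridge()
        part = greedy_modularity(net)
        comm = {g: g for g in net.nodes}  # replay merges from singletons
        for (u, v), q_after in part.merge_history:
            for g, c in comm.items():
                if c == v:
                    comm[g] = u
            assert q_after == pytest.approx(modularity(net, comm))

    def test_edgeless_network_yields_singletons_with_warning(self):
        net = Network(["a", "b", "c"], np.zeros((3, 3), bool), 0.5)
        with pytest.warns(UserWarning, match="edgeless"):
            part = greedy_modularity(net)
        assert len(set(part.membership.values())) == 3

    def test_invariant_to_node_input_order(self, rng):
        nodes = [f"g{i}" for i in range(10)]
        adj = np.triu(rng.random((10, 10)) < 0.4, 1)
        adj = adj | adj.T
        net1 = Network(nodes, adj, 0.5)
        perm = list(rng.permutation(10))
        net2 = Network([nodes[i] for i in perm], adj[np.ix_(perm, perm)], 0.5)
        p1, p2 = greedy_modularity(net1), greedy_modularity(net2)
        assert partition_similarity(p1.membership, p2.membership) == pytest.approx(1.0)
        assert p1.q == pytest.approx(p2.q)

    def test_agrees_with_networkx_cnm_on_separated_cliques(self):
        net, left, right = two_cliques_with_bridge()
        nx_comms = nx.community.greedy_modularity_communities(net.to_networkx())
        ours = greedy_modularity(net).communities().values()
        assert {frozenset(c) for c in nx_comms} == {frozenset(c) for c in ours}


class TestModulesAndSimilarity:
    def test_size_filter_keeps_modules_above_five_genes(self):
        membership = {}
        for cid, size in enumerate((10, 6, 5, 2)):
            for k in range(size):
                membership[f"c{cid}_{k}"] = cid
        mods = regulatory_modules(membership, min_size=6)
        assert [m.size for m in mods] == [10, 6]

    def test_min_size_one_returns_everything(self):
        mods = regulatory_modules({"a": 0, "b": 1}, min_size=1)
        assert len(mods) == 2
        assert regulatory_modules({}, min_size=1) == []

    def test_ari_identical_and_degenerate_pairs(self):
        p1 = {f"g{i}": i for i in range(6)}
        p2 = {f"g{i}": 0 for i in range(6)}
        assert partition_similarity(p1, p1) == 1.0
        assert partition_similarity(p1, p2) == pytest.approx(0.0)

    def test_ari_invariant_to_label_permutation(self):
        p1 = {"a": 0, "b": 0, "c": 1, "d": 1}
        p2 = {"a": 7, "b": 7, "c": 3, "d": 3}
        assert partition_similarity(p1, p2) == 1.0

    def test_node_set_mismatch_rejected(self):
        with pytest.raises(ValueError):
            partition_similarity({"a": 0}, {"b": 0})
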