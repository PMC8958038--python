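"""Unit and property tests for the graph substrate."""

import networkx as nx
import numpy as np
import pytest

from netrepurpose.network import (
    EmptyNetworkError,
    GeneNetwork,
    NetworkError,
    NetworkParseError,
    build_degree_bins,
    crosstalk_count,
    load_network,
    max_crosstalk,
    sample_degree_matched,
    shortest_path_from_set,
    shuffle_preserving_degree,
)

from conftest import (
    brute_crosstalk,
    brute_max_crosstalk,
    brute_min_distance_from_set,
    random_instance,
)


# ---------------------------------------------------------------------------
# loading


def _write(tmp_path, text, name="net.tsv"):
    p = tmp_path / name
    p.write_text(text)
    return p


class TestLoadNetwork:
    def test_threshold_and_self_loop_rule(self, tmp_path):
        p = _write(tmp_path, "A\tB\t0.9\nB\tC\t0.5\nA\tA\t0.95\n")
        net = load_network(p, confidence_threshold=0.8)
        assert net.node_set == {"A", "B"}
        assert set(map(frozenset, net.edges())) == {frozenset(("A", "B"))}

    def test_zero_threshold_keeps_all(self, tmp_path):
        p = _write(tmp_path, "A\tB\t0.9\nB\tC\t0.5\nA\tA\t0.95\n")
        net = load_network(p, confidence_threshold=0.0)
        assert net.node_set == {"A", "B", "C"}
        assert net.n_edges == 2

    def test_reversed_duplicate_collapses(self, tmp_path):
        p = _write(tmp_path, "A\tB\t0.9\nB\tA\t0.9\n")
        assert load_network(p, 0.5).n_edges == 1

    def test_header_and_comments_skipped(self, tmp_path):
        p = _write(tmp_path, "# comment\nnodeA\tnodeB\tconf\nA\tB\t0.9\n")
        net = load_network(p, 0.8)
        assert net.n_edges == 1

    def test_no_confidence_column_keeps_everything(self, tmp_path):
        p = _write(tmp_path, "A\tB\nB\tC\n")
        assert load_network(p, 0.8).n_edges == 2

    def test_malformed_row_names_line(self, tmp_path):
        p = _write(tmp_path, "A\tB\t0.9\nA\n")
        with pytest.raises(NetworkParseError, match="line 2"):
            load_network(p, 0.5)

    def test_empty_after_threshold_raises(self, tmp_path):
        p = _write(tmp_path, "A\tB\t0.1\n")
        with pytest.raises(EmptyNetworkError):
            load_network(p, 0.8)

    def test_largest_component_flag(self, tmp_path):
        p = _write(tmp_path, "A\tB\nB\tC\nX\tY\n")
        net = load_network(p, 0.0, keep_largest_component=True)
        assert net.node_set == {"A", "B", "C"}


def test_self_loop_rejected_at_construction():
    g = nx.Graph([("a", "a")])
    with pytest.raises(NetworkError):
        GeneNetwork(g)


# ---------------------------------------------------------------------------
# shortest paths


class TestShortestPathFromSet:
    def test_path_graph_examples(self, path5):
        d = shortest_path_from_set(path5, {"1"})
        assert d["4"] == 3
        d = shortest_path_from_set(path5, {"1", "5"})
        assert d["3"] == 2
        assert d["1"] == 0 and d["5"] == 0

    def test_empty_sources_error(self, path5):
        with pytest.raises(NetworkError):
            shortest_path_from_set(path5, set())

    def test_unreachable_nodes_absent(self):
        net = GeneNetwork.from_edges([("a", "b")], nodes=["a", "b", "z"])
        assert "z" not in shortest_path_from_set(net, {"a"})

    @pytest.mark.parametrize("seed", range(10))
    def test_agrees_with_per_source_bfs(self, seed):
        net, set_a, _ = random_instance(seed)
        assert shortest_path_from_set(net, set_a) == brute_min_distance_from_set(net, set_a)


# ---------------------------------------------------------------------------
# crosstalk


class TestCrosstalk:
    def test_path_examples(self):
        net = GeneNetwork.from_edges([("1", "2"), ("2", "3")])
        assert crosstalk_count(net, {"1"}, {"2"}) == 1
        assert crosstalk_count(net, {"1", "3"}, {"2"}) == 2
        assert crosstalk_count(net, {"1", "2"}, {"1", "2"}) == 1

    def test_empty_set_gives_zero(self, path5):
        assert crosstalk_count(path5, set(), {"1"}) == 0

    def test_max_crosstalk_examples(self):
        assert max_crosstalk({"a", "b", "c"}, {"x", "y", "z", "w"}) == 12
        assert max_crosstalk({"1", "2"}, {"1", "2"}) == 1
        assert max_crosstalk({"1", "2"}, {"2", "3"}) == 3

    @pytest.mark.parametrize("seed", range(30))
    def test_matches_bruteforce_including_overlap(self, seed):
        net, set_a, set_b = random_instance(seed)
        assert crosstalk_count(net, set_a, set_b) == brute_crosstalk(net, set_a, set_b)
        assert max_crosstalk(set_a, set_b) == brute_max_crosstalk(set_a, set_b)

    @pytest.mark.parametrize("seed", range(10))
    def test_symmetry_and_bound(self, seed):
        net, set_a, set_b = random_instance(seed)
        x = crosstalk_count(net, set_a, set_b)
        assert x == crosstalk_count(net, set_b, set_a)
        assert x <= max_crosstalk(set_a, set_b)

    def test_equality_on_complete_graph(self):
        g = nx.complete_graph(6)
        net = GeneNetwork(nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}))
        a, b = {"n0", "n1", "n2"}, {"n2", "n3"}
        assert crosstalk_count(net, a, b) == max_crosstalk(a, b)


# ---------------------------------------------------------------------------
# degree bins


class TestDegreeBins:
    def test_remainder_boundary_not_merged(self):
        # 250 nodes, bin_size 100: remainder 50 is not < 50, kept separate
        net = GeneNetwork.from_edges(
            [(f"n{i}", f"n{i+1}") for i in range(249)]
        )
        bins = build_degree_bins(net, 100)
        assert [len(b) for b in bins.bins] == [100, 100, 50]

    def test_small_remainder_merged(self):
        # 240 nodes: remainder 40 < 50 merges into the previous bin
        net = GeneNetwork.from_edges([(f"n{i}", f"n{i+1}") for i in range(239)])
        bins = build_degree_bins(net, 100)
        assert [len(b) for b in bins.bins] == [100, 140]

    def test_exact_fit_single_bin(self):
        net = GeneNetwork.from_edges([(f"n{i}", f"n{i+1}") for i in range(99)])
        bins = build_degree_bins(net, 100)
        assert [len(b) for b in bins.bins] == [100]

    def test_bins_partition_nodes_in_degree_order(self, ba300):
        bins = build_degree_bins(ba300, 50)
        seen = [n for chunk in bins.bins for n in chunk]
        assert set(seen) == ba300.node_set and len(seen) == ba300.n_nodes
        degs = [ba300.degree(n) for n in seen]
        assert degs == sorted(degs)

    def test_ties_broken_deterministically(self):
        # all nodes degree 1: binning must still be reproducible
        net = GeneNetwork.from_edges([(f"a{i}", f"b{i}") for i in range(30)])
        b1 = build_degree_bins(net, 10)
        b2 = build_degree_bins(net, 10)
        assert b1.bins == b2.bins
        assert all(len(c) == 10 for c in b1.bins)

    def test_oversized_bin_size_single_bin(self, path5):
        bins = build_degree_bins(path5, 100)
        assert len(bins.bins) == 1


class TestSampleDegreeMatched:
    def test_forced_sample_returns_reference(self, path5):
        bins = build_degree_bins(path5, 2)
        rng = np.random.default_rng(0)
        # bin of the two degree-1 endpoints has exactly size 2
        ref = {"1", "5"}
        assert sample_degree_matched(path5, bins, ref, rng) == ref

    def test_size_and_bin_composition_preserved(self, ba300):
        bins = build_degree_bins(ba300, 30)
        rng = np.random.default_rng(3)
        ref = set(list(ba300.node_set)[:17])
        for _ in range(5):
            sample = sample_degree_matched(ba300, bins, ref, rng)
            assert len(sample) == len(ref)
            assert bins.counts_for(sample) == bins.counts_for(ref)

    def test_deterministic_given_seed(self, ba300):
        bins = build_degree_bins(ba300, 30)
        ref = set(sorted(ba300.node_set)[:10])
        s1 = sample_degree_matched(ba300, bins, ref, np.random.default_rng(7))
        s2 = sample_degree_matched(ba300, bins, ref, np.random.default_rng(7))
        assert s1 == s2


# ---------------------------------------------------------------------------
# shuffling


class TestShufflePreservingDegree:
    @pytest.mark.parametrize("seed", range(5))
    def test_degree_sequence_and_simplicity(self, seed):
        g = nx.gnp_random_graph(60, 0.1, seed=seed)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        net = GeneNetwork(g)
        out = shuffle_preserving_degree(net, rng=np.random.default_rng(seed))
        assert out.node_set == net.node_set
        assert {n: out.degree(n) for n in out.node_set} == {
            n: net.degree(n) for n in net.node_set
        }
        assert nx.number_of_selfloops(out.graph) == 0
        assert out.n_edges == net.n_edges  # simple graph: no collapsed duplicates

    def test_four_cycle_stays_two_regular(self):
        net = GeneNetwork.from_edges([("a", "b"), ("b", "c"), ("c", "d"), ("d", "a")])
        out = shuffle_preserving_degree(net, rng=np.random.default_rng(1))
        assert all(out.degree(n) == 2 for n in "abcd")
        assert out.n_edges == 4

    def test_edge_set_actually_changes(self):
        g = nx.gnp_random_graph(100, 0.1, seed=2)
        g = nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes})
        net = GeneNetwork(g)
        out = shuffle_preserving_degree(net, rng=np.random.default_rng(2))
        assert set(map(frozenset, out.edges())) != set(map(frozenset, net.edges()))

    def test_deterministic_given_seed(self):
        g = nx.gnp_random_graph(40, 0.15, seed=3)
        net = GeneNetwork(nx.relabel_nodes(g, {i: f"n{i}" for i in g.nodes}))
        e1 = set(map(frozenset, shuffle_preserving_degree(net, rng=np.random.default_rng(5)).edges()))
        e2 = set(map(frozenset, shuffle_preserving_degree(net, rng=np.random.default_rng(5)).edges()))
        assert e1 == e2

    def test_requires_explicit_rng(self, path5):
        with pytest.raises(ValueError):
            shuffle_preserving_degree(path5)
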