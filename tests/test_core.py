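"""The clustering algorithm: node statistics, seeds, refinement, cuts."""

import itertools

import networkx as nx
import pytest
from hypothesis import given
from hypothesis import strategies as st

from lrclust.core import (
    ClusterConfig,
    Community,
    NodeStats,
    SeedThresholds,
    best_partition,
    cluster_graph,
    cutoff_schedule,
    delta_cc,
    generate_partition,
    local_clco,
    node_stats,
    resolve_pair,
    seed_communities,
    seed_thresholds,
    select_seeds,
    union_clco,
)


def brute_force_clco(graph: nx.Graph, node: int) -> float:
    """Oracle: enumerate all neighbour pairs and count realised edges."""
    nbrs = [v for v in graph.adj[node] if v != node]
    if len(nbrs) <= 1:
        return 1.0
    links = sum(1 for u, v in itertools.combinations(nbrs, 2)
                if graph.has_edge(u, v))
    return 2.0 * links / (len(nbrs) * (len(nbrs) - 1))


class TestLocalClco:
    def test_triangle_node_is_fully_clustered(self):
        g = nx.complete_graph(3)
        assert local_clco(g, 0) == 1.0

    def test_star_center_is_zero(self):
        g = nx.star_graph(3)
        assert local_clco(g, 0) == 0.0

    def test_half_connected_neighbourhood(self):
        g = nx.Graph([("a", v) for v in "bcde"]
                     + [("b", "c"), ("b", "d"), ("c", "d")])
        assert local_clco(g, "a") == pytest.approx(0.5)

    def test_isolated_and_degree_one_nodes_are_one(self):
        g = nx.Graph()
        g.add_node(0)
        g.add_edge(1, 2)
        assert local_clco(g, 0) == 1.0
        assert local_clco(g, 1) == 1.0

    def test_missing_node_raises(self):
        with pytest.raises(KeyError):
            local_clco(nx.Graph(), 42)

    @given(st.integers(1, 12), st.floats(0.0, 1.0), st.integers(0, 10 ** 6))
    def test_matches_bruteforce_oracle(self, n, p, seed):
        g = nx.gnp_random_graph(n, p, seed=seed)
        for node in g.nodes:
            assert local_clco(g, node) == pytest.approx(
                brute_force_clco(g, node), abs=1e-12)


class TestNodeStats:
    def test_butterfly(self, butterfly):
        stats = node_stats(butterfly, rounding=2)
        assert stats[3].degree == 4 and stats[3].clco == pytest.approx(0.33)
        for node in (1, 2, 4, 5):
            assert stats[node].degree == 2 and stats[node].clco == 1.0

    def test_empty_graph(self):
        assert node_stats(nx.Graph()) == {}

    def test_four_clique(self, four_clique):
        stats = node_stats(four_clique)
        assert all(s.degree == 3 and s.clco == 1.0 for s in stats.values())


class TestSeedThresholds:
    def test_nearest_rank_99th_percentile(self):
        stats = {i: NodeStats(degree=i, clco=1.0) for i in range(1, 101)}
        assert seed_thresholds(stats).theta1 == 99

    def test_uniform_clco_gives_itself(self):
        stats = {i: NodeStats(degree=3, clco=1.0) for i in range(10)}
        assert seed_thresholds(stats).theta2 == 1.0

    def test_single_node_degenerate(self):
        stats = {7: NodeStats(degree=5, clco=0.25)}
        thr = seed_thresholds(stats)
        assert thr.theta1 == 5 and thr.theta2 == 0.25

    def test_empty_stats_raise(self):
        with pytest.raises(ValueError):
            seed_thresholds({})

    def test_at_most_one_percent_outside(self):
        stats = {i: NodeStats(degree=i % 17, clco=(i % 11) / 10)
                 for i in range(500)}
        thr = seed_thresholds(stats)
        degs = [s.degree for s in stats.values()]
        clcos = [s.clco for s in stats.values()]
        assert sum(d > thr.theta1 for d in degs) <= 0.01 * len(degs)
        assert sum(c < thr.theta2 for c in clcos) <= 0.01 * len(clcos)


class TestCutoffSchedule:
    def test_butterfly_schedule(self, butterfly):
        sched = cutoff_schedule(node_stats(butterfly), rounding=2)
        assert sched.values == (1.0, 0.33)

    def test_rounding_collapses_close_values(self):
        stats = {0: NodeStats(2, 0.501), 1: NodeStats(2, 0.499)}
        assert cutoff_schedule(stats, rounding=2).values == (0.5,)

    def test_cap_preserves_endpoints(self):
        stats = {i: NodeStats(2, round(0.001 + i * 0.0019, 4))
                 for i in range(500)}
        sched = cutoff_schedule(stats, rounding=4, max_values=100)
        values = sorted({round(s.clco, 4) for s in stats.values()},
                        reverse=True)
        assert len(sched.values) == 100
        assert sched.values[0] == values[0]
        assert sched.values[-1] == values[-1]

    def test_all_zero_clco_gives_empty_schedule(self):
        stats = {i: NodeStats(3, 0.0) for i in range(4)}
        assert cutoff_schedule(stats).values == ()


class TestSelectSeeds:
    def test_butterfly_low_cutoff_orders_hub_first(self, butterfly):
        stats = node_stats(butterfly)
        thr = seed_thresholds(stats)
        seeds = select_seeds(stats, thr, 0.33)
        assert set(seeds) == {1, 2, 3, 4, 5}
        assert seeds[0] == 3  # highest degree first

    def test_butterfly_top_cutoff_excludes_shared_node(self, butterfly):
        stats = node_stats(butterfly)
        thr = seed_thresholds(stats)
        assert select_seeds(stats, thr, 1.0) == [1, 2, 4, 5]

    def test_star_guard_excludes_high_degree_low_clco_hub(self):
        stats = {0: NodeStats(degree=100, clco=0.1)}
        stats.update({i: NodeStats(degree=5, clco=0.8) for i in range(1, 5)})
        thr = SeedThresholds(theta1=50, theta2=0.5)
        assert 0 not in select_seeds(stats, thr, 0.05)
        # a node AT theta2 is never guard-excluded
        stats[0] = NodeStats(degree=100, clco=0.5)
        assert 0 in select_seeds(stats, thr, 0.05)


class TestSeedCommunities:
    def test_neighbourhood_of_hub(self, butterfly):
        (comm,) = seed_communities(butterfly, [3])
        assert comm.members == {1, 2, 3, 4, 5}
        assert comm.seed == 3

    def test_identical_neighbourhoods_deduplicated(self, butterfly):
        comms = seed_communities(butterfly, [1, 2])
        assert len(comms) == 1
        assert comms[0].seed == 1 and comms[0].members == {1, 2, 3}

    def test_isolated_seed_is_singleton(self):
        g = nx.Graph()
        g.add_node(9)
        (comm,) = seed_communities(g, [9])
        assert comm.members == {9}


class TestUnionAndDelta:
    def test_butterfly_union(self, butterfly):
        assert union_clco(butterfly, {1, 2, 3}, {3, 4, 5}) == pytest.approx(0.6)

    def test_clique_union_is_one(self, four_clique):
        assert union_clco(four_clique, {0, 1}, {2, 3}) == 1.0

    def test_edgeless_union_is_zero(self):
        g = nx.Graph()
        g.add_nodes_from([0, 1])
        assert union_clco(g, {0}, {1}) == 0.0

    def test_tiny_union_raises(self):
        g = nx.complete_graph(3)
        with pytest.raises(ValueError):
            union_clco(g, {0}, {0})

    def test_delta_cc_zero_when_unchanged(self, butterfly):
        assert delta_cc(butterfly, {1, 2, 3}, {1, 2, 3}) == 0.0

    def test_delta_cc_butterfly_growth(self, butterfly):
        assert delta_cc(butterfly, {1, 2, 3}, {1, 2, 3, 4, 5}) == pytest.approx(-0.4)

    def test_delta_cc_gain_from_edgeless_pair(self):
        # {0,1} has no edge (coefficient 0); adding their common
        # neighbour 2 raises the set coefficient to 2/3
        g = nx.Graph([(0, 2), (1, 2)])
        assert delta_cc(g, {0, 1}, {0, 1, 2}) == pytest.approx(2 / 3)

    def test_delta_cc_subset_violation(self, butterfly):
        with pytest.raises(ValueError):
            delta_cc(butterfly, {1, 4}, {1, 2, 3})


class TestResolvePair:
    def test_merge_when_union_reaches_cutoff(self, butterfly):
        c1 = Community(1, {1, 2, 3})
        c2 = Community(4, {3, 4, 5})
        res = resolve_pair(butterfly, c1, c2, cutoff=0.33)
        assert res.action == "merge"
        assert res.first.members == {1, 2, 3, 4, 5}
        assert res.edges_removed == 0

    def test_split_ties_resolve_to_smaller_seed(self, butterfly):
        g = butterfly.copy()
        res = resolve_pair(g, Community(1, {1, 2, 3}), Community(4, {3, 4, 5}),
                           cutoff=1.0)
        assert res.action == "split"
        assert res.first.members == {1, 2, 3}
        assert res.second.members == {4, 5}
        assert res.edges_removed == 2
        assert not g.has_edge(3, 4) and not g.has_edge(3, 5)

    def test_split_assigns_block_to_denser_side(self):
        g = nx.Graph([(3, 1), (3, 2), (3, 6), (3, 4), (3, 5)])
        res = resolve_pair(g, Community(1, {1, 2, 3, 6}), Community(4, {3, 4, 5}),
                           cutoff=1.0)
        assert res.action == "split"
        assert 3 in res.first.members
        assert res.second.members == {4, 5}
        assert res.edges_removed == 2

    def test_disjoint_pair_is_contract_violation(self, butterfly):
        with pytest.raises(ValueError):
            resolve_pair(butterfly, Community(1, {1, 2}), Community(4, {4, 5}), 0.5)


class TestGeneratePartition:
    def test_butterfly_low_cutoff_merges(self, butterfly):
        stats = node_stats(butterfly)
        thr = seed_thresholds(stats)
        part = generate_partition(butterfly, stats, thr, 0.33)
        assert sorted(map(sorted, part.communities)) == [[1, 2, 3, 4, 5]]
        assert part.cut_size == 0

    def test_butterfly_top_cutoff_splits(self, butterfly):
        stats = node_stats(butterfly)
        thr = seed_thresholds(stats)
        part = generate_partition(butterfly, stats, thr, 1.0)
        assert sorted(map(sorted, part.communities)) == [[1, 2, 3], [4, 5]]
        assert part.cut_size == 2

    def test_clique_is_one_community(self, four_clique):
        stats = node_stats(four_clique)
        thr = seed_thresholds(stats)
        for cutoff in (0.5, 1.0):
            part = generate_partition(four_clique, stats, thr, cutoff)
            assert len(part.communities) == 1 and part.cut_size == 0


class TestBestPartition:
    def test_butterfly_minimum_cut_wins(self, butterfly):
        stats = node_stats(butterfly)
        thr = seed_thresholds(stats)
        sched = cutoff_schedule(stats)
        part = best_partition(butterfly, stats, thr, sched)
        assert part.cut_size == 0
        assert part.cutoff == pytest.approx(0.33)
        assert sorted(map(sorted, part.communities)) == [[1, 2, 3, 4, 5]]

    def test_six_cycle_empty_schedule_one_cluster(self):
        g = nx.cycle_graph(6)
        stats = node_stats(g)
        assert all(s.clco == 0.0 for s in stats.values())
        sched = cutoff_schedule(stats)
        assert sched.values == ()
        part = best_partition(g, stats, seed_thresholds(stats), sched)
        assert part.cut_size == 0
        assert sorted(map(sorted, part.communities)) == [[0, 1, 2, 3, 4, 5]]


class TestClusterGraph:
    def test_two_disjoint_cliques_recovered(self):
        g = nx.disjoint_union(nx.complete_graph(5), nx.complete_graph(5))
        out = cluster_graph(g, ClusterConfig(preprocess=False))
        assert sorted(map(sorted, out.clusters)) == [
            [0, 1, 2, 3, 4], [5, 6, 7, 8, 9]]

    def test_butterfly_with_and_without_preprocessing(self, butterfly):
        merged = cluster_graph(butterfly, ClusterConfig(preprocess=False))
        assert sorted(map(sorted, merged.clusters)) == [[1, 2, 3, 4, 5]]
        shattered = cluster_graph(butterfly)
        assert sorted(map(sorted, shattered.clusters)) == [[1, 2], [3], [4, 5]]

    def test_empty_graph(self):
        assert cluster_graph(nx.Graph()).clusters == []

    @given(st.integers(1, 22), st.floats(0.05, 0.95), st.integers(0, 10 ** 6))
    def test_output_is_partition_of_node_set(self, n, p, seed):
        g = nx.gnp_random_graph(n, p, seed=seed)
        for config in (ClusterConfig(), ClusterConfig(preprocess=False),
                       ClusterConfig(per_node_split=True)):
            out = cluster_graph(g, config)
            nodes = [u for c in out.clusters for u in c]
            assert sorted(nodes) == sorted(g.nodes)

    @given(st.lists(st.integers(2, 8), min_size=1, max_size=6))
    def test_disjoint_cliques_recovered_exactly(self, sizes):
        g = nx.Graph()
        expected, start = [], 0
        for s in sizes:
            members = list(range(start, start + s))
            g.add_edges_from(itertools.combinations(members, 2))
            expected.append(members)
            start += s
        out = cluster_graph(g, ClusterConfig(preprocess=False))
        assert sorted(map(sorted, out.clusters)) == expected

    def test_deterministic_across_runs_and_threads(self):
        g = nx.gnp_random_graph(40, 0.2, seed=7)
        runs = [cluster_graph(g, ClusterConfig(threads=t)) for t in (1, 1, 3)]
        assert runs[0] == runs[1] == runs[2]

    def test_global_percentile_scope_runs(self, butterfly):
        out = cluster_graph(butterfly, ClusterConfig(percentile_scope="global",
                                                     preprocess=False))
        assert sorted(u for c in out.clusters for u in c) == [1, 2, 3, 4, 5]
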