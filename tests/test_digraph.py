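"""Graph model, components, strong bridges, and the two auxiliary graphs."""

import pytest
from hypothesis import given, settings, strategies as hst

from safetigs import (
    CircularWalk,
    Digraph,
    NotStronglyConnectedError,
    Walk,
    random_strongly_connected,
    split_nodes,
    strong_bridges,
    strongly_connected_components,
    subdivide_edges,
)


class TestDigraph:
    def test_adjacency_is_consistent_and_sorted(self):
        g = Digraph([(2, 1), (1, 2), (1, 3), (3, 1), (3, 3)])
        assert g.n == 3 and g.m == 5
        assert g.successors(1) == (2, 3)
        assert g.predecessors(1) == (2, 3)
        assert g.successors(3) == (1, 3)
        for u, v in g.edges:
            assert v in g.successors(u) and u in g.predecessors(v)

    def test_parallel_edges_collapse(self):
        g = Digraph([(1, 2), (1, 2), (2, 1)])
        assert g.m == 2

    def test_without_edge_keeps_nodes(self):
        g = Digraph([(1, 2), (2, 1)])
        h = g.without_edge(1, 2)
        assert h.nodes == (1, 2) and h.m == 1
        with pytest.raises(KeyError):
            g.without_edge(2, 2)


class TestWalks:
    def test_lengths_and_classification(self):
        w = Walk((1, 2, 3))
        assert w.length == 2 and w.is_proper and w.is_path and not w.is_cycle
        c = Walk((2, 3, 1, 2))
        assert c.is_circular and c.is_cycle
        bad = Walk((1, 2, 1, 2))
        assert not bad.is_path and not bad.is_cycle

    def test_cycle_canonicalization_picks_smallest_rotation(self):
        assert Walk((2, 3, 1, 2)).canonical() == Walk((1, 2, 3, 1))
        assert Walk((1, 2, 3)).canonical() == Walk((1, 2, 3))

    def test_circular_walk_wraparound_subwalks(self):
        c = CircularWalk((1, 2, 3, 1))
        assert c.d == 3
        assert c.subwalk(2, 2) == Walk((3, 1, 2))
        assert c.subwalk(0, 3) == Walk((1, 2, 3, 1))
        assert c.contains_subwalk(Walk((3, 1, 2)))
        assert not c.contains_subwalk(Walk((1, 2, 3, 1, 2)))  # longer than d
        with pytest.raises(ValueError):
            c.subwalk(0, 4)


class TestComponents:
    @pytest.mark.parametrize(
        "edges,expected",
        [
            ([(1, 2), (2, 3), (3, 1)], 1),
            ([(1, 2), (2, 1), (3, 4), (4, 3)], 2),
            ([("c", "a1"), ("a1", "a2"), ("a2", "c"),
              ("c", "b1"), ("b1", "b2"), ("b2", "c")], 1),
        ],
    )
    def test_scc_counts(self, edges, expected):
        assert len(strongly_connected_components(Digraph(edges))) == expected

    def test_scc_order_is_deterministic(self):
        comps = strongly_connected_components(
            Digraph([(4, 3), (3, 4), (1, 2), (2, 1), (2, 3)])
        )
        assert [min(c) for c in comps] == sorted(min(c) for c in comps)


class TestStrongBridges:
    def test_every_cycle_edge_is_a_bridge(self, triangle):
        assert strong_bridges(triangle) == frozenset(triangle.edges)

    def test_bowtie_all_edges_are_bridges(self, bowtie):
        assert strong_bridges(bowtie) == frozenset(bowtie.edges)

    def test_edge_with_alternative_path_is_not_a_bridge(self):
        g = Digraph([(1, 2), (2, 1), (2, 3), (3, 1)])
        assert (2, 1) not in strong_bridges(g)
        assert {(1, 2), (2, 3), (3, 1)} <= strong_bridges(g)

    def test_requires_strong_connectivity(self):
        with pytest.raises(NotStronglyConnectedError):
            strong_bridges(Digraph([(1, 2)]))

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=hst.integers(0, 10**6), n=hst.integers(2, 7),
           extra=hst.integers(0, 6))
    def test_matches_removal_recount_oracle(self, seed, n, extra):
        g = random_strongly_connected(n, min(extra, n * n - 2 * n), seed)
        base = len(strongly_connected_components(g))
        expected = frozenset(
            e for e in g.edges
            if len(strongly_connected_components(g.without_edge(*e))) > base
        )
        assert strong_bridges(g) == expected


class TestSubdivision:
    @pytest.mark.parametrize(
        "edges,nodes_out,edges_out",
        [
            ([(1, 2), (2, 3), (3, 1)], 6, 6),
            ([(1, 1)], 2, 2),
            ([("c", "a1"), ("a1", "a2"), ("a2", "c"),
              ("c", "b1"), ("b1", "b2"), ("b2", "c")], 11, 12),
        ],
    )
    def test_sizes(self, edges, nodes_out, edges_out):
        g = Digraph(edges)
        sd = subdivide_edges(g)
        assert sd.graph.n == g.n + g.m == nodes_out
        assert sd.graph.m == 2 * g.m == edges_out

    def test_midpoints_have_unique_neighbours(self, bowtie):
        sd = subdivide_edges(bowtie)
        for (u, v), x in sd.edge_node.items():
            assert sd.graph.predecessors(x) == (("n", u),)
            assert sd.graph.successors(x) == (("n", v),)

    def test_lift_unlift_roundtrip(self, bowtie):
        sd = subdivide_edges(bowtie)
        for w in (Walk(("c", "a1", "a2")), Walk(("c", "a1", "a2", "c"))):
            lifted = sd.lift(w)
            lifted.validate_in(sd.graph)
            assert sd.unlift(lifted) == w

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=hst.integers(0, 10**6), n=hst.integers(1, 7))
    def test_preserves_strong_connectivity(self, seed, n):
        g = random_strongly_connected(n, seed % max(n * n - 2 * n, 1), seed)
        assert subdivide_edges(g).graph.is_strongly_connected()
        assert split_nodes(g).graph.is_strongly_connected()


class TestNodeSplit:
    @pytest.mark.parametrize(
        "edges,nodes_out,edges_out",
        [
            ([(1, 2), (2, 3), (3, 1)], 6, 6),
            ([(1, 1)], 2, 2),
            ([("c", "a1"), ("a1", "a2"), ("a2", "c"),
              ("c", "b1"), ("b1", "b2"), ("b2", "c")], 10, 11),
        ],
    )
    def test_sizes(self, edges, nodes_out, edges_out):
        g = Digraph(edges)
        ns = split_nodes(g)
        assert ns.graph.n == 2 * g.n == nodes_out
        assert ns.graph.m == g.n + g.m == edges_out

    def test_structure(self):
        g = Digraph([(1, 2), (2, 1)])
        gp = split_nodes(g).graph
        assert gp.has_edge((1, "in"), (1, "out"))
        assert gp.has_edge((1, "out"), (2, "in"))
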