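"""The safe-walk scan: soundness, completeness, structure of the output."""

import pytest

from safetigs import (
    Digraph,
    NotStronglyConnectedError,
    Walk,
    edge_safe_pairs,
    enumerate_safe_walks,
    fixture,
    node_safe_pairs,
    safe_walks_per_component,
    subdivide_edges,
)
from safetigs.oracle import brute_all_safe_walks
from safetigs.synthetic import exhaustive_strongly_connected


class TestCycleGraphs:
    @pytest.mark.parametrize("n", [1, 2, 3, 6])
    def test_every_subwalk_is_safe_in_both_modes(self, n):
        g = fixture("cycle", n=n)
        for pairs in (node_safe_pairs(g), edge_safe_pairs(g)):
            assert pairs.cover.d == n
            expected = {(i, k) for k in range(1, n + 1) for i in range(n)}
            assert set(pairs.pairs()) == expected


class TestKnownGraphs:
    def test_bowtie_node_mode(self, bowtie):
        walks = enumerate_safe_walks(node_safe_pairs(bowtie))
        assert Walk(("c", "a1", "a2", "c")).canonical() in walks
        assert Walk(("c", "b1", "b2", "c")).canonical() in walks
        # an omnitig without certificates is not safe
        assert Walk(("a2", "c", "b1")) not in walks

    def test_bowtie_edge_mode(self, bowtie):
        walks = enumerate_safe_walks(edge_safe_pairs(bowtie))
        assert Walk(("c", "a1", "a2", "c")).canonical() in walks
        assert Walk(("a2", "c", "b1")) not in walks

    def test_chorded_triangle_single_edge_safe(self, chorded_triangle):
        pairs = node_safe_pairs(chorded_triangle)
        walks = enumerate_safe_walks(pairs)
        assert Walk((1, 2)) in walks

    def test_every_single_edge_is_edge_safe(self, small_random_graphs):
        for g in small_random_graphs[:10]:
            walks = enumerate_safe_walks(edge_safe_pairs(g))
            for e in g.edges:
                assert Walk(e).canonical() in walks


class TestOracleEquivalence:
    @pytest.mark.parametrize("mode", ["node", "edge"])
    def test_exhaustive_small_graphs(self, mode):
        for n in (1, 2, 3):
            for g in exhaustive_strongly_connected(n):
                pairs = node_safe_pairs(g) if mode == "node" else edge_safe_pairs(g)
                assert enumerate_safe_walks(pairs) == brute_all_safe_walks(
                    g, mode
                ), g.edges

    @pytest.mark.parametrize("mode", ["node", "edge"])
    def test_random_graphs(self, mode, small_random_graphs):
        for g in small_random_graphs:
            pairs = node_safe_pairs(g) if mode == "node" else edge_safe_pairs(g)
            assert enumerate_safe_walks(pairs) == brute_all_safe_walks(
                g, mode
            ), g.edges


class TestStructuralInvariants:
    @pytest.mark.parametrize("mode", ["node", "edge"])
    def test_safe_walks_are_paths_or_cycles(self, mode, small_random_graphs):
        for g in small_random_graphs:
            pairs = node_safe_pairs(g) if mode == "node" else edge_safe_pairs(g)
            for w in enumerate_safe_walks(pairs):
                assert w.is_path or w.is_cycle

    @pytest.mark.parametrize("mode", ["node", "edge"])
    def test_downward_closure_of_levels(self, mode, small_random_graphs):
        for g in small_random_graphs:
            pairs = node_safe_pairs(g) if mode == "node" else edge_safe_pairs(g)
            d = pairs.cover.d
            for k in range(2, pairs.cap + 1):
                for i in pairs.S(k):
                    assert i in pairs.S(k - 1)
                    assert (i + 1) % d in pairs.S(k - 1)

    def test_unitigs_are_contained_in_edge_safe_walks(self, small_random_graphs):
        """Classical unitigs (maximal paths with degree-one internal nodes)
        are always edge-safe, so the scan must cover each of them."""
        for g in small_random_graphs:
            safe = enumerate_safe_walks(edge_safe_pairs(g))
            for u in _unitigs(g):
                assert any(_contained(u, w) for w in safe), (g.edges, u)

    def test_subdivision_reduction(self, small_random_graphs):
        """w is edge-safe in G iff S(w) is node-safe in S(G)."""
        for g in small_random_graphs[:12]:
            sd = subdivide_edges(g)
            edge_side = enumerate_safe_walks(edge_safe_pairs(g))
            node_side = enumerate_safe_walks(node_safe_pairs(sd.graph))
            lifted = {sd.lift(w).canonical() for w in edge_side}
            assert lifted <= node_side
            for w in node_side:
                w2 = _rotate_to_lifted(sd, w)
                if w2 is not None:
                    assert sd.unlift(w2).canonical() in edge_side


def _unitigs(g: Digraph):
    """Maximal paths whose internal nodes have in-degree = out-degree = 1."""
    def internal(v):
        return len(g.successors(v)) == 1 and len(g.predecessors(v)) == 1

    out = []
    for u, v in g.edges:
        if u == v:
            continue
        nodes = [u, v]
        while internal(nodes[-1]):
            nxt = g.successors(nodes[-1])[0]
            if nxt in nodes:
                break
            nodes.append(nxt)
        while internal(nodes[0]):
            prv = g.predecessors(nodes[0])[0]
            if prv in nodes:
                break
            nodes.insert(0, prv)
        out.append(Walk(tuple(nodes)))
    return out


def _contained(small: Walk, big: Walk) -> bool:
    if big.is_circular:
        from safetigs import CircularWalk

        return CircularWalk(big.nodes).contains_subwalk(small)
    ks, kb = small.length, big.length
    return ks <= kb and any(
        big.nodes[i:i + ks + 1] == small.nodes for i in range(kb - ks + 1)
    )


def _rotate_to_lifted(sd, w: Walk):
    """Rotate a cycle of S(G) so it starts at an original node; None when the
    walk is not a lifting (e.g. a path with mid-point endpoints)."""
    if sd.is_lifted(w):
        return w
    if w.is_cycle:
        per = w.nodes[:-1]
        for r in range(len(per)):
            cand = Walk(per[r:] + per[:r] + (per[r],))
            if sd.is_lifted(cand):
                return cand
    return None


class TestMultiComponentHandling:
    def test_two_disjoint_triangles_edge_mode(self):
        g = Digraph([(1, 2), (2, 3), (3, 1), (4, 5), (5, 6), (6, 4)])
        results = safe_walks_per_component(g, "edge")
        assert len(results) == 2

    def test_cross_edge_rejected_in_edge_mode(self):
        g = Digraph([(1, 2), (2, 1), (3, 4), (4, 3), (2, 3)])
        with pytest.raises(NotStronglyConnectedError):
            safe_walks_per_component(g, "edge")

    def test_node_on_no_cycle_rejected_in_node_mode(self):
        g = Digraph([(1, 2), (2, 1), (2, 3)])
        with pytest.raises(NotStronglyConnectedError):
            safe_walks_per_component(g, "node")

    def test_two_sccs_with_cross_edge_allowed_in_node_mode(self):
        g = Digraph([(1, 2), (2, 1), (3, 4), (4, 3), (2, 3)])
        results = safe_walks_per_component(g, "node")
        walks = {w for p in results for w in enumerate_safe_walks(p)}
        assert Walk((1, 2, 1)).canonical() in walks
        # the cross edge lies on no circular walk: never safe
        assert Walk((2, 3)) not in walks
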