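"""Constant-time queries for the two omnitig conditions.

An omnitig extension step asks one question of the graph: *is there a proper
path from the last node of the walk back to its second node whose first edge
differs from the walk's last edge and whose last edge differs from the walk's
first edge?*  (With the convention that a v-v "path" means a cycle through v.)
If no such bypassing path exists, gluing two overlapping omnitigs yields an
omnitig.

:class:`PathQueryTable` answers that question in O(1) after per-row
preprocessing.  A simple x1-z path with last edge (q, z) exists if and only
if q is an in-neighbour of z reachable from x1 without passing through z, so
one BFS per (forbidden-first-edge, target) pair -- computed lazily and cached
-- answers all queries exactly under simple-path semantics.

The second omnitig condition ("each edge is the only path between its
endpoints") reduces to strong bridges, except for self-loops, which the SCC
recount cannot see: a self-loop is the only v-v path precisely when v lies on
no other cycle.
"""

from __future__ import annotations

from .digraph import (
    Digraph,
    Edge,
    Walk,
    require_strongly_connected,
    scc_index,
    strong_bridges,
)

__all__ = ["PathQueryTable", "build_path_query_table", "only_path_edge_test",
           "OnlyPathPredicate", "omnitig_extension_check"]


class PathQueryTable:
    """O(1) oracle for first/last-edge-constrained path existence.

    ``query(e1, e2)`` with e1 = (x1, y1), e2 = (w, z) returns True iff the
    graph has a proper x1-z path whose first edge is not e1 and whose last
    edge is not e2.  When x1 == z a "path" is a cycle through x1, following
    the usual convention.  Defined for all ordered edge pairs, including
    e1 == e2.

    Rows are keyed by (e1, z): each row is the set of in-neighbours q of z
    such that (q, z) survives the removal of e1 and q is reachable from x1 in
    G - e1 avoiding z (z's removal is skipped when z == x1, since a simple
    path starting at x1 never revisits it).  A row costs one BFS, O(m); a
    query is then a set lookup.
    """

    def __init__(self, g: Digraph):
        self._g = g
        self._rows: dict[tuple[Edge, object], frozenset] = {}

    @property
    def graph(self) -> Digraph:
        return self._g

    def _row(self, e1: Edge, z) -> frozenset:
        key = (e1, z)
        row = self._rows.get(key)
        if row is None:
            g = self._g
            x1 = e1[0]
            reach = g.reachable_from(
                x1, skip_edge=e1, skip_node=(z if z != x1 else None)
            )
            row = frozenset(
                q for q in g.predecessors(z) if (q, z) != e1 and q in reach
            )
            self._rows[key] = row
        return row

    def query(self, e1: Edge, e2: Edge) -> bool:
        if not self._g.has_edge(*e1):
            raise KeyError(e1)
        if not self._g.has_edge(*e2):
            raise KeyError(e2)
        w, z = e2
        row = self._row(e1, z)
        # any reachable in-edge of z other than the forbidden last edge
        if w in row:
            return len(row) > 1
        return len(row) > 0


def build_path_query_table(g: Digraph) -> PathQueryTable:
    return PathQueryTable(g)


class OnlyPathPredicate:
    """Constant-time test: is edge (x, y) the only x-y path?

    For ordinary edges this is exactly the strong-bridge property.  A
    self-loop (v, v) is the only cycle through v iff v is on no cycle of
    G - loop, i.e. v's component in G - loop is trivial.
    """

    def __init__(self, g: Digraph):
        require_strongly_connected(g)
        self._g = g
        self._bridges = strong_bridges(g)
        self._loop_only: dict[Edge, bool] = {}
        for v in g.nodes:
            if g.has_edge(v, v):
                comp = scc_index(g, skip_edge=(v, v))
                size = sum(1 for c in comp.values() if c == comp[v])
                self._loop_only[(v, v)] = size == 1
    def __call__(self, e: Edge) -> bool:
        if not self._g.has_edge(*e):
            raise KeyError(e)
        if e[0] == e[1]:
            return self._loop_only[e]
        return e in self._bridges


def only_path_edge_test(g: Digraph) -> OnlyPathPredicate:
    return OnlyPathPredicate(g)


def omnitig_extension_check(table: PathQueryTable, w: Walk) -> bool:
    """Decide whether ``w`` extends two overlapping omnitigs into an omnitig.

    Preconditions (the caller's dynamic program guarantees them): w has
    length >= 2 and its two overlapping sub-walks of length |w| - 1 are
    omnitigs.  Then w is an omnitig iff there is no v_t-v_1 path with first
    edge != e_t and last edge != e_0 -- one table query.
    """
    if w.length < 2:
        raise ValueError("extension check applies to walks of length >= 2")
    edges = w.edges
    return not table.query(edges[-1], edges[0])
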