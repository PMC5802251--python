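"""The safe-and-complete scan: all safe walks of a strongly connected graph.

The algorithm materialises one covering circular walk C and decides, for
every start index i and length k, whether the sub-walk C(i, k) occurs in
every covering collection of circular walks.  The characterization being
checked is: C(i, k) is safe iff it is an omnitig (no bypassing path; in node
mode additionally every edge is the only path between its endpoints) and it
has at least one certificate.  Omnitig-ness is extended incrementally
(a walk is an omnitig iff its two length-(k-1) sub-walks are and one
path query fails), certificate non-emptiness is a sliding-window query, and
every safe walk of the graph shows up as some marked (i, k) because safe
walks are sub-walks of C.

Every reported walk must be a path or a cycle; the scan enforces this
explicitly, which is also what keeps the certificate-intersection shortcut
(Cert of a walk = intersection over its items) valid.
"""

from __future__ import annotations

from dataclasses import dataclass

from .certificates import node_certificates, edge_certificates, window_scan
from .covering import edge_covering_circular_walk, node_covering_circular_walk
from .digraph import (
    CircularWalk,
    Digraph,
    Node,
    NotStronglyConnectedError,
    Walk,
    require_strongly_connected,
    strongly_connected_components,
)
from .pathquery import build_path_query_table, only_path_edge_test

__all__ = ["SafePairs", "node_safe_pairs", "edge_safe_pairs",
           "enumerate_safe_walks", "safe_walks_per_component"]


@dataclass(frozen=True)
class SafePairs:
    """Output encoding of the scan: a covering circular walk C plus, for each
    length k in 1..cap, the set S_k of start indices i with C(i, k) safe."""

    graph: Digraph
    mode: str
    cover: CircularWalk
    cap: int
    levels: tuple[frozenset[int], ...]

    def S(self, k: int) -> frozenset[int]:
        """The set of start indices of safe sub-walks of length k."""
        if not 1 <= k <= self.cap:
            raise ValueError(f"k must be in 1..{self.cap}")
        if k > len(self.levels):
            return frozenset()
        return self.levels[k - 1]

    def pairs(self):
        """All safe (i, k) pairs, ordered by (k, i)."""
        for k in range(1, self.cap + 1):
            for i in sorted(self.S(k)):
                yield (i, k)

    def walk(self, i: int, k: int) -> Walk:
        return self.cover.subwalk(i, k)


def _is_path_or_cycle(cover: CircularWalk, i: int, k: int) -> bool:
    first = cover.node_at(i)
    seen = {first}
    for j in range(1, k):
        v = cover.node_at(i + j)
        if v in seen:
            return False
        seen.add(v)
    last = cover.node_at(i + k)
    return last == first or last not in seen


def _scan(g: Digraph, mode: str) -> SafePairs:
    require_strongly_connected(g)
    if mode == "node":
        cover = node_covering_circular_walk(g)
        table_certs = node_certificates(g)
    else:
        cover = edge_covering_circular_walk(g)
        table_certs = edge_certificates(g)
    d = cover.d
    cap = min(g.n, d)
    window = window_scan(table_certs, cover, cap)
    pq = build_path_query_table(g)

    if mode == "node":
        only_path = only_path_edge_test(g)
        s1 = frozenset(
            i for i in range(d)
            if only_path(cover.edge_at(i)) and window.query(i, 1)
        )
    else:
        # a single edge always certifies itself, and the bypass condition is
        # vacuous at length one
        s1 = frozenset(range(d))

    levels = [s1]
    for k in range(2, cap + 1):
        prev = levels[-1]
        if not prev:
            break
        nxt = set()
        for i in prev:
            if (i + 1) % d not in prev:
                continue
            if not _is_path_or_cycle(cover, i, k):
                continue
            if not window.query(i, k):
                continue
            if pq.query(cover.edge_at(i + k - 1), cover.edge_at(i)):
                continue  # a bypassing path exists: not an omnitig
            nxt.add(i)
        levels.append(frozenset(nxt))
    return SafePairs(g, mode, cover, cap, tuple(levels))


def node_safe_pairs(g: Digraph) -> SafePairs:
    """All node-safe walks of g, encoded over a node-covering circular walk."""
    return _scan(g, "node")


def edge_safe_pairs(g: Digraph) -> SafePairs:
    """All edge-safe walks of g, encoded over an edge-covering circular walk."""
    return _scan(g, "edge")


def enumerate_safe_walks(pairs: SafePairs) -> frozenset[Walk]:
    """Expand the (i, k) encoding into the set of distinct safe walks.

    Cycles are canonicalized to their lexicographically smallest rotation, so
    all safe rotations of one cycle collapse into one class.
    """
    return frozenset(
        pairs.walk(i, k).canonical() for (i, k) in pairs.pairs()
    )


def safe_walks_per_component(g: Digraph, mode: str) -> list[SafePairs]:
    """Run the scan per strongly connected component of a general input.

    Node mode requires every node to lie on a cycle (a node covered by no
    circular walk admits no covering reconstruction); cross-component edges
    lie on no cycle and are ignored.  Edge mode requires the graph to be a
    disjoint union of strongly connected graphs, i.e. no cross-component
    edges at all.
    """
    comps = strongly_connected_components(g)
    subgraphs = [g.subgraph(c) for c in comps]
    if mode == "node":
        for c, sub in zip(comps, subgraphs):
            if sub.m == 0:
                (v,) = c
                raise NotStronglyConnectedError(
                    f"node {v!r} lies on no cycle: no covering reconstruction"
                )
    else:
        within = sum(sub.m for sub in subgraphs)
        if within != g.m:
            raise NotStronglyConnectedError(
                "edge mode needs a disjoint union of strongly connected "
                "graphs (found edges between components)"
            )
    return [_scan(sub, mode) for sub in subgraphs]
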