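"""Covering circular walks and minimum-length covering reconstructions.

A *metagenomic reconstruction* of a strongly connected graph is a collection
of circular walks that together cover every node (node mode) or every edge
(edge mode) -- the model of "all circular genomes in the sample together
explain all reads".  The safety algorithm only needs *one* covering circular
walk to scan; this module builds a deterministic one by stitching BFS
shortest paths between sorted targets.  It also solves the optimisation
variant: a covering reconstruction of minimum total length, via an exact
minimum-cost circulation with unit lower bounds, decomposed into cycles.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx

from .digraph import (
    CircularWalk,
    Digraph,
    Edge,
    Node,
    NotStronglyConnectedError,
    Walk,
    require_strongly_connected,
    split_nodes,
)

__all__ = [
    "Reconstruction",
    "node_covering_circular_walk",
    "edge_covering_circular_walk",
    "min_length_reconstruction",
]


def _bfs_path(g: Digraph, s: Node, t: Node) -> list[Node]:
    """Shortest s-t path; BFS explores successors in sorted order, so among
    equally short paths the lexicographically first one is returned."""
    if s == t:
        return [s]
    parent: dict[Node, Node] = {s: s}
    q: deque[Node] = deque([s])
    while q:
        x = q.popleft()
        for y in g.successors(x):
            if y in parent:
                continue
            parent[y] = x
            if y == t:
                path = [t]
                while path[-1] != s:
                    path.append(parent[path[-1]])
                return path[::-1]
            q.append(y)
    raise NotStronglyConnectedError(f"no path from {s!r} to {t!r}")


def node_covering_circular_walk(g: Digraph) -> CircularWalk:
    """A circular walk covering every node, of length n <= d <= n^2.

    Visits the nodes in sorted order, connecting consecutive targets by BFS
    shortest paths and closing back to the start.  Deterministic.
    """
    require_strongly_connected(g)
    ns = g.nodes
    if g.m == 0:
        raise NotStronglyConnectedError(
            "graph admits no covering circular walk (no edges)"
        )
    walk: list[Node] = [ns[0]]
    for target in list(ns[1:]) + [ns[0]]:
        walk.extend(_bfs_path(g, walk[-1], target)[1:])
    if len(walk) == 1:
        # single node: the only possible circular walk is its self-loop
        v = ns[0]
        if not g.has_edge(v, v):
            raise NotStronglyConnectedError(
                "single node without self-loop admits no circular walk"
            )
        walk.append(v)
    return CircularWalk(tuple(walk))


def edge_covering_circular_walk(g: Digraph) -> CircularWalk:
    """A circular walk traversing every edge at least once, d <= mn.

    Traverses the edges in sorted order, routing between them by BFS shortest
    paths.  Deterministic.
    """
    require_strongly_connected(g)
    if g.m == 0:
        raise NotStronglyConnectedError(
            "graph admits no covering circular walk (no edges)"
        )
    es = g.edges
    walk: list[Node] = [es[0][0]]
    for u, v in es:
        walk.extend(_bfs_path(g, walk[-1], u)[1:])
        walk.append(v)
    walk.extend(_bfs_path(g, walk[-1], walk[0])[1:])
    return CircularWalk(tuple(walk))


# ---------------------------------------------------------------------------
# Minimum total length reconstruction via min-cost circulation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Reconstruction:
    """A covering collection of cycles with its total length."""

    walks: tuple[CircularWalk, ...]
    mode: str  # "node" | "edge"

    @property
    def total_length(self) -> int:
        return sum(w.d for w in self.walks)

    def covers(self, g: Digraph) -> bool:
        if self.mode == "node":
            covered = {v for w in self.walks for v in w.nodes}
            return covered >= set(g.nodes)
        covered_e = {
            w.edge_at(i) for w in self.walks for i in range(w.d)
        }
        return covered_e >= set(g.edges)


def _solve_circulation(
    edges: list[Edge], lower: dict[Edge, int], cost: dict[Edge, int]
) -> dict[Edge, int]:
    """Exact min-cost circulation with per-edge lower bounds (no capacities).

    Standard transformation: force the lower bound l on (u, v), which leaves
    residual node imbalances (the tail must receive l, the head supply l),
    then solve an ordinary min-cost flow for the residual with networkx's
    network simplex (exact on integers).  Self-loops carry exactly their
    lower bound: residual flow on a positive-cost self-loop is never useful.
    """
    flow_net = nx.DiGraph()
    demand: dict[Node, int] = {}
    for u, v in edges:
        demand.setdefault(u, 0)
        demand.setdefault(v, 0)
        l = lower.get((u, v), 0)
        if u != v:
            demand[u] += l
            demand[v] -= l
            flow_net.add_edge(u, v, weight=cost.get((u, v), 0))
    for x, b in demand.items():
        flow_net.add_node(x, demand=b)
    try:
        _, flow = nx.network_simplex(flow_net)
    except nx.NetworkXUnfeasible as exc:  # pragma: no cover - guarded by pre
        raise RuntimeError("circulation infeasible on covered input") from exc
    result: dict[Edge, int] = {}
    for u, v in edges:
        f = lower.get((u, v), 0)
        if u != v:
            f += flow.get(u, {}).get(v, 0)
        result[(u, v)] = f
    return result


def _decompose_cycles(flow: dict[Edge, int]) -> list[list[Node]]:
    """Decompose an integral circulation into simple cycles.

    Repeatedly starts from the smallest node with positive out-flow, walks
    positive-flow edges choosing the smallest successor, and cancels the
    first cycle closed.  Deterministic; terminates because each extraction
    strictly reduces total flow.
    """
    residual: dict[Node, dict[Node, int]] = {}
    for (u, v), f in flow.items():
        if f > 0:
            residual.setdefault(u, {})[v] = f
    cycles: list[list[Node]] = []
    while residual:
        start = min(residual)
        trail = [start]
        pos = {start: 0}
        while True:
            x = trail[-1]
            y = min(residual[x])
            if y in pos:
                cyc = trail[pos[y]:] + [y]
                for a, b in zip(cyc, cyc[1:]):
                    residual[a][b] -= 1
                    if residual[a][b] == 0:
                        del residual[a][b]
                        if not residual[a]:
                            del residual[a]
                cycles.append(cyc)
                break
            pos[y] = len(trail)
            trail.append(y)
    return cycles


def min_length_reconstruction(g: Digraph, mode: str = "node") -> Reconstruction:
    """Covering reconstruction (collection of cycles) of minimum total length.

    Node mode: on the node-split graph G', split edges get demand 1 / cost 0
    and original edges demand 0 / cost 1, so the circulation cost equals the
    total length in G.  Edge mode: every edge of G gets demand 1 / cost 1
    directly.  The optimal circulation is decomposed into cycles.
    """
    if mode not in ("node", "edge"):
        raise ValueError(f"unknown mode {mode!r}")
    require_strongly_connected(g)
    if g.m == 0:
        raise NotStronglyConnectedError("graph admits no covering reconstruction")
    if mode == "node":
        gp = split_nodes(g).graph
        lower = {}
        cost = {}
        for e in gp.edges:
            (x, side_a), (y, side_b) = e
            if x == y and side_a == "in" and side_b == "out":
                lower[e] = 1
                cost[e] = 0
            else:
                cost[e] = 1
        flow = _solve_circulation(list(gp.edges), lower, cost)
        raw_cycles = _decompose_cycles(flow)
        walks = []
        for cyc in raw_cycles:
            # every (x, "in") is followed by (x, "out"): read off the originals
            originals = [tok[0] for tok in cyc[:-1] if tok[1] == "out"]
            walks.append(CircularWalk(tuple(originals) + (originals[0],)))
    else:
        lower = {e: 1 for e in g.edges}
        cost = {e: 1 for e in g.edges}
        flow = _solve_circulation(list(g.edges), lower, cost)
        walks = [CircularWalk(tuple(cyc)) for cyc in _decompose_cycles(flow)]
    walks.sort(key=lambda w: (w.d, w.nodes))
    rec = Reconstruction(tuple(walks), mode)
    assert rec.covers(g), "internal error: reconstruction does not cover"
    return rec
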