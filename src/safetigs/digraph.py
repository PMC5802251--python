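"""Directed-graph data model for assembly-graph safety analysis.

The graphs handled here are the usual abstraction of a (node-centric) assembly
graph: a directed graph without parallel edges, in which self-loops and pairs
of opposite edges are allowed.  Node identifiers are opaque but must be
mutually sortable within one graph so that every derived object (component
lists, covering walks, reported contigs) is deterministic.

Besides the graph itself this module holds the two auxiliary constructions the
safety machinery needs:

* ``subdivide_edges`` -- S(G), each edge split once by a fresh mid-point node;
  reduces edge-safety questions to node-safety questions.
* ``split_nodes`` -- G', each node x split into (x_in, x_out) joined by an
  edge; turns "cycles through a node" into "cycles through an edge", which is
  how per-node certificates are computed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Hashable, Iterable, Iterator, Mapping

import networkx as nx

Node = Hashable
Edge = tuple[Node, Node]

__all__ = [
    "Digraph",
    "scc_index",
    "Walk",
    "CircularWalk",
    "SubdivisionMap",
    "NodeSplitMap",
    "NotStronglyConnectedError",
    "strongly_connected_components",
    "strong_bridges",
    "subdivide_edges",
    "split_nodes",
]


class NotStronglyConnectedError(ValueError):
    """Raised when an operation requires a strongly connected input graph."""


class Digraph:
    """An immutable directed graph without parallel edges.

    Self-loops are allowed; at most one edge exists per ordered pair.
    Adjacency lists are kept sorted, so all iteration is deterministic.
    """

    __slots__ = ("_nodes", "_edges", "_succ", "_pred")

    def __init__(self, edges: Iterable[Edge] = (), nodes: Iterable[Node] = ()):
        succ: dict[Node, set[Node]] = {}
        pred: dict[Node, set[Node]] = {}
        edge_set: set[Edge] = set()
        for v in nodes:
            succ.setdefault(v, set())
            pred.setdefault(v, set())
        for u, v in edges:
            edge_set.add((u, v))
            succ.setdefault(u, set()).add(v)
            succ.setdefault(v, set())
            pred.setdefault(v, set()).add(u)
            pred.setdefault(u, set())
        self._nodes: tuple[Node, ...] = tuple(sorted(succ))
        self._edges: frozenset[Edge] = frozenset(edge_set)
        self._succ: dict[Node, tuple[Node, ...]] = {
            v: tuple(sorted(s)) for v, s in succ.items()
        }
        self._pred: dict[Node, tuple[Node, ...]] = {
            v: tuple(sorted(p)) for v, p in pred.items()
        }

    # -- basic accessors -------------------------------------------------

    @property
    def nodes(self) -> tuple[Node, ...]:
        return self._nodes

    @property
    def edges(self) -> tuple[Edge, ...]:
        return tuple(sorted(self._edges))

    @property
    def n(self) -> int:
        return len(self._nodes)

    @property
    def m(self) -> int:
        return len(self._edges)

    def successors(self, v: Node) -> tuple[Node, ...]:
        return self._succ[v]

    def predecessors(self, v: Node) -> tuple[Node, ...]:
        return self._pred[v]

    def has_node(self, v: Node) -> bool:
        return v in self._succ

    def has_edge(self, u: Node, v: Node) -> bool:
        return (u, v) in self._edges

    def __contains__(self, v: Node) -> bool:
        return v in self._succ

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Digraph):
            return NotImplemented
        return self._nodes == other._nodes and self._edges == other._edges

    def __hash__(self) -> int:
        return hash((self._nodes, self._edges))

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Digraph(n={self.n}, m={self.m})"

    # -- derived graphs --------------------------------------------------

    def without_edge(self, u: Node, v: Node) -> "Digraph":
        """Copy of the graph with edge (u, v) removed (nodes kept)."""
        if (u, v) not in self._edges:
            raise KeyError((u, v))
        return Digraph((e for e in self._edges if e != (u, v)), self._nodes)

    def subgraph(self, keep: Iterable[Node]) -> "Digraph":
        """Induced subgraph on ``keep`` (edges with both endpoints kept)."""
        ks = set(keep)
        return Digraph(
            ((u, v) for (u, v) in self._edges if u in ks and v in ks), ks
        )

    def to_networkx(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self._nodes)
        g.add_edges_from(self._edges)
        return g

    def is_strongly_connected(self) -> bool:
        return len(strongly_connected_components(self)) <= 1

    def reachable_from(
        self, source: Node, skip_edge: Edge | None = None, skip_node: Node | None = None
    ) -> frozenset[Node]:
        """Nodes reachable from ``source`` (including it), optionally with one
        edge and/or one node deleted.  ``skip_node`` may not be the source."""
        if skip_node == source:
            raise ValueError("cannot skip the BFS source")
        seen = {source}
        stack = [source]
        while stack:
            x = stack.pop()
            for y in self._succ[x]:
                if y in seen or y == skip_node or (x, y) == skip_edge:
                    continue
                seen.add(y)
                stack.append(y)
        return frozenset(seen)


def require_strongly_connected(g: Digraph) -> None:
    if not g.is_strongly_connected():
        raise NotStronglyConnectedError(
            "operation requires a strongly connected graph"
        )


# ---------------------------------------------------------------------------
# Walks
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Walk:
    """A walk, stored as its node sequence.

    Because the host graph has no parallel edges, consecutive node pairs
    determine the edges uniquely, so the edge sequence is derived.  A walk of
    length 0 is a single node; walks of length >= 1 are *proper*.
    """

    nodes: tuple[Node, ...]

    def __post_init__(self) -> None:
        if len(self.nodes) == 0:
            raise ValueError("a walk has at least one node")
        object.__setattr__(self, "nodes", tuple(self.nodes))

    @property
    def length(self) -> int:
        """Number of edges."""
        return len(self.nodes) - 1

    @property
    def edges(self) -> tuple[Edge, ...]:
        ns = self.nodes
        return tuple((ns[i], ns[i + 1]) for i in range(len(ns) - 1))

    @property
    def is_proper(self) -> bool:
        return self.length >= 1

    @property
    def is_circular(self) -> bool:
        return self.length >= 1 and self.nodes[0] == self.nodes[-1]

    @property
    def is_path(self) -> bool:
        return len(set(self.nodes)) == len(self.nodes)

    @property
    def is_cycle(self) -> bool:
        """Circular with all nodes distinct except the repeated endpoint."""
        return self.is_circular and len(set(self.nodes)) == self.length

    def validate_in(self, g: Digraph) -> None:
        for u, v in self.edges:
            if not g.has_edge(u, v):
                raise ValueError(f"({u!r}, {v!r}) is not an edge of the graph")

    def canonical(self) -> "Walk":
        """Canonical representative: cycles are rotated to the
        lexicographically smallest rotation; other walks are unchanged."""
        if not self.is_cycle:
            return self
        per = self.nodes[:-1]
        t = len(per)
        best = min(per[i:] + per[:i] for i in range(t))
        return Walk(best + (best[0],))

    def __str__(self) -> str:
        return ",".join(str(v) for v in self.nodes)


@dataclass(frozen=True)
class CircularWalk:
    """A circular walk C = (v_0, ..., v_d = v_0) with wrap-around indexing.

    ``subwalk(i, k)`` is C(i, k): the sub-walk starting at v_i of length k,
    defined for 0 <= i < d and 0 <= k <= d.
    """

    nodes: tuple[Node, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nodes", tuple(self.nodes))
        if len(self.nodes) < 2 or self.nodes[0] != self.nodes[-1]:
            raise ValueError("circular walk needs v_d == v_0 and d >= 1")

    @property
    def d(self) -> int:
        return len(self.nodes) - 1

    def node_at(self, i: int) -> Node:
        return self.nodes[i % self.d]

    def edge_at(self, i: int) -> Edge:
        i %= self.d
        return (self.nodes[i], self.nodes[(i + 1) % self.d])

    def subwalk(self, i: int, k: int) -> Walk:
        if not 0 <= i < self.d:
            raise IndexError(i)
        if not 0 <= k <= self.d:
            raise ValueError(f"sub-walk length {k} outside 0..{self.d}")
        return Walk(tuple(self.node_at(i + j) for j in range(k)) + (self.node_at(i + k),)) \
            if k > 0 else Walk((self.node_at(i),))

    def contains_subwalk(self, w: Walk) -> bool:
        """Wrap-around sub-walk containment; requires len(w) <= d."""
        k = w.length
        if k > self.d:
            return False
        ws = w.nodes
        return any(
            all(self.node_at(i + j) == ws[j] for j in range(k + 1))
            for i in range(self.d)
        )

    def as_walk(self) -> Walk:
        return Walk(self.nodes)

    def __str__(self) -> str:
        return ",".join(str(v) for v in self.nodes)


# ---------------------------------------------------------------------------
# Components and strong bridges
# ---------------------------------------------------------------------------


def scc_index(g: Digraph, skip_edge: Edge | None = None) -> dict[Node, int]:
    """Map each node to a strongly-connected-component id, optionally with
    one edge ignored.  Iterative Tarjan; no graph copying, which is what
    makes the per-edge-deleted recomputations (certificates, strong bridges)
    affordable."""
    index: dict[Node, int] = {}
    low: dict[Node, int] = {}
    comp: dict[Node, int] = {}
    onstack: set[Node] = set()
    stack: list[Node] = []
    counter = 0
    ccount = 0
    for root in g.nodes:
        if root in index:
            continue
        index[root] = low[root] = counter
        counter += 1
        stack.append(root)
        onstack.add(root)
        frames: list[tuple[Node, Iterator[Node]]] = [(root, iter(g.successors(root)))]
        while frames:
            v, it = frames[-1]
            advanced = False
            for w in it:
                if (v, w) == skip_edge:
                    continue
                if w not in index:
                    index[w] = low[w] = counter
                    counter += 1
                    stack.append(w)
                    onstack.add(w)
                    frames.append((w, iter(g.successors(w))))
                    advanced = True
                    break
                if w in onstack and index[w] < low[v]:
                    low[v] = index[w]
            if advanced:
                continue
            frames.pop()
            if frames:
                u = frames[-1][0]
                if low[v] < low[u]:
                    low[u] = low[v]
            if low[v] == index[v]:
                while True:
                    w = stack.pop()
                    onstack.remove(w)
                    comp[w] = ccount
                    if w == v:
                        break
                ccount += 1
    return comp


def strongly_connected_components(g: Digraph) -> tuple[frozenset[Node], ...]:
    """SCC partition, ordered by the smallest node in each component."""
    comp = scc_index(g)
    groups: dict[int, set[Node]] = {}
    for v, c in comp.items():
        groups.setdefault(c, set()).add(v)
    return tuple(sorted((frozenset(s) for s in groups.values()), key=min))


def strong_bridges(g: Digraph) -> frozenset[Edge]:
    """Edges whose removal increases the number of strongly connected
    components.  Computed by per-edge removal and SCC recount.

    Note: a self-loop never changes the SCC partition, so self-loops are
    never strong bridges under this definition; the only-path predicate in
    :mod:`safetigs.pathquery` handles them separately.
    """
    require_strongly_connected(g)
    base = len(set(scc_index(g).values()))
    out = set()
    for e in g.edges:
        if len(set(scc_index(g, skip_edge=e).values())) > base:
            out.add(e)
    return frozenset(out)


# ---------------------------------------------------------------------------
# S(G): subdivide every edge once
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SubdivisionMap:
    """The subdivision graph S(G) together with walk lifting.

    Every node of G appears in S(G) as ``("n", v)``; every edge (u, v) of G
    becomes a mid-point node ``("e", u, v)`` with edges (u -> x_uv -> v).
    S(G) has n + m nodes and 2m edges.  ``lift``/``unlift`` translate walks
    between G and S(G); lifting is a bijection onto the walks of S(G) whose
    endpoints are original nodes.
    """

    original: Digraph
    graph: Digraph
    edge_node: Mapping[Edge, Node] = field(hash=False)

    @staticmethod
    def node_token(v: Node) -> Node:
        return ("n", v)

    def lift(self, w: Walk) -> Walk:
        out: list[Node] = [self.node_token(w.nodes[0])]
        for e in w.edges:
            out.append(self.edge_node[e])
            out.append(self.node_token(e[1]))
        return Walk(tuple(out))

    def unlift(self, w: Walk) -> Walk:
        ns = w.nodes
        if len(ns) % 2 == 0 or any(ns[i][0] != ("n" if i % 2 == 0 else "e") for i in range(len(ns))):
            raise ValueError("not a lifted walk (must start and end at original nodes)")
        return Walk(tuple(tok[1] for tok in ns[::2]))

    def is_lifted(self, w: Walk) -> bool:
        ns = w.nodes
        return len(ns) % 2 == 1 and all(
            ns[i][0] == ("n" if i % 2 == 0 else "e") for i in range(len(ns))
        )


def subdivide_edges(g: Digraph) -> SubdivisionMap:
    edge_node: dict[Edge, Node] = {(u, v): ("e", u, v) for (u, v) in g.edges}
    edges: list[Edge] = []
    for (u, v), x in edge_node.items():
        edges.append((("n", u), x))
        edges.append((x, ("n", v)))
    sg = Digraph(edges, (("n", v) for v in g.nodes))
    return SubdivisionMap(original=g, graph=sg, edge_node=edge_node)


# ---------------------------------------------------------------------------
# G': split every node into (in, out)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class NodeSplitMap:
    """The node-split graph G' used for per-node certificates.

    Each node x of G becomes ``(x, "in")`` and ``(x, "out")`` joined by the
    split edge; each original edge (y, z) becomes ((y, "out"), (z, "in")).
    G' has 2n nodes and n + m edges, and every cycle of G through x maps to a
    cycle of G' through the split edge of x.
    """

    original: Digraph
    graph: Digraph

    @staticmethod
    def split_edge(x: Node) -> Edge:
        return ((x, "in"), (x, "out"))


def split_nodes(g: Digraph) -> NodeSplitMap:
    edges: list[Edge] = [((x, "in"), (x, "out")) for x in g.nodes]
    edges.extend(((y, "out"), (z, "in")) for (y, z) in g.edges)
    return NodeSplitMap(original=g, graph=Digraph(edges))
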