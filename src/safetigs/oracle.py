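"""Brute-force ground truth by exhaustive path and cycle enumeration.

These routines implement the safety *characterization* directly -- a walk is
safe iff it is an omnitig and some node (edge) certifies it, where every
clause is decided by enumerating simple paths and simple cycles.  Nothing
here shares code with the efficient scan; this is the reference the test
suite compares against.  All entry points are guarded to small graphs.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import networkx as nx

from .digraph import CircularWalk, Digraph, Edge, Node, Walk

__all__ = [
    "enumerate_simple_cycles",
    "constrained_path_exists",
    "brute_is_omnitig",
    "brute_certificate_set",
    "brute_is_safe",
    "brute_all_safe_walks",
    "brute_maximal_safe_walks",
    "brute_min_reconstruction_length",
]

MAX_NODES = 12


def _guard(g: Digraph) -> None:
    if g.n > MAX_NODES:
        raise ValueError(
            f"brute-force oracle is limited to {MAX_NODES} nodes (got {g.n})"
        )


@lru_cache(maxsize=64)
def _cycles(g: Digraph) -> tuple[tuple[Node, ...], ...]:
    """All simple cycles as closed node tuples (v0 .. vt v0), canonical
    rotation (smallest node first), sorted."""
    out = []
    for cyc in nx.simple_cycles(g.to_networkx()):
        i = cyc.index(min(cyc))
        rot = tuple(cyc[i:] + cyc[:i])
        out.append(rot + (rot[0],))
    return tuple(sorted(set(out)))


@lru_cache(maxsize=4096)
def _paths(g: Digraph, u: Node, v: Node) -> tuple[tuple[Node, ...], ...]:
    """All proper simple u-v walks under the usual convention:
    ordinary simple paths when u != v, rotations of simple cycles through u
    when u == v."""
    if u == v:
        out = []
        for cyc in _cycles(g):
            per = cyc[:-1]
            for i, x in enumerate(per):
                if x == u:
                    out.append(per[i:] + per[:i] + (u,))
        return tuple(sorted(out))
    return tuple(
        sorted(tuple(p) for p in nx.all_simple_paths(g.to_networkx(), u, v))
    )


def enumerate_simple_cycles(g: Digraph) -> tuple[CircularWalk, ...]:
    """All simple cycles (self-loops included), canonical rotation."""
    _guard(g)
    return tuple(CircularWalk(c) for c in _cycles(g))


def constrained_path_exists(
    g: Digraph, u: Node, v: Node, forbid_first: Edge, forbid_last: Edge
) -> bool:
    """Is there a proper u-v path (cycle through u when u == v) whose first
    edge differs from ``forbid_first`` and last edge from ``forbid_last``?"""
    _guard(g)
    for p in _paths(g, u, v):
        if (p[0], p[1]) != forbid_first and (p[-2], p[-1]) != forbid_last:
            return True
    return False


def _edge_on_cycle(cycle: tuple[Node, ...], e: Edge) -> bool:
    return any((cycle[i], cycle[i + 1]) == e for i in range(len(cycle) - 1))


def _walk_in_cycle(cycle: tuple[Node, ...], w: tuple[Node, ...]) -> bool:
    t = len(cycle) - 1
    k = len(w) - 1
    if k > t:
        return False
    per = cycle[:t]
    return any(
        all(per[(i + j) % t] == w[j] for j in range(k + 1)) for i in range(t)
    )


def brute_is_omnitig(g: Digraph, w: Walk, mode: str = "node") -> bool:
    """Definition-level omnitig test.

    Condition (1), both modes: no proper v_j-v_i path with first edge != e_j
    and last edge != e_{i-1}, for all 1 <= i <= j <= t.  Condition (2), node
    mode only: each edge e_j is the only v_j-v_{j+1} path.
    """
    _guard(g)
    w.validate_in(g)
    ns, es = w.nodes, w.edges
    t = w.length - 1
    for i in range(1, t + 1):
        for j in range(i, t + 1):
            if constrained_path_exists(g, ns[j], ns[i], es[j], es[i - 1]):
                return False
    if mode == "edge":
        return True
    for j in range(t + 1):
        if any(p != (ns[j], ns[j + 1]) for p in _paths(g, ns[j], ns[j + 1])):
            return False
    return True


def brute_certificate_set(g: Digraph, w: Walk, mode: str = "node") -> frozenset:
    """Certificates by direct cycle enumeration: the nodes (edges) all of
    whose cycles contain w as a wrap-around sub-walk."""
    _guard(g)
    w.validate_in(g)
    cycles = _cycles(g)
    out = set()
    if mode == "node":
        for x in g.nodes:
            through = [c for c in cycles if x in c[:-1]]
            if through and all(_walk_in_cycle(c, w.nodes) for c in through):
                out.add(x)
    else:
        for e in g.edges:
            through = [c for c in cycles if _edge_on_cycle(c, e)]
            if through and all(_walk_in_cycle(c, w.nodes) for c in through):
                out.add(e)
    return frozenset(out)


def brute_is_safe(g: Digraph, w: Walk, mode: str = "node") -> bool:
    return brute_is_omnitig(g, w, mode) and bool(
        brute_certificate_set(g, w, mode)
    )


def _candidate_walks(g: Digraph):
    """Every wrap-around sub-walk of every simple cycle, lengths 1..n.

    Complete: a safe walk needs a certificate, hence fits in some cycle.
    Each rotation/occurrence is its own candidate -- safety is a property of
    the exact walk, and rotations of one cycle can differ in safety.
    """
    n = g.n
    seen = set()
    for c in _cycles(g):
        t = len(c) - 1
        per = c[:t]
        for k in range(1, min(n, t) + 1):
            for i in range(t):
                w = tuple(per[(i + j) % t] for j in range(k + 1))
                if w not in seen:
                    seen.add(w)
                    yield Walk(w)


def brute_all_safe_walks(g: Digraph, mode: str = "node") -> frozenset[Walk]:
    """The set of distinct safe walks (cycles canonicalized)."""
    _guard(g)
    return frozenset(
        w.canonical() for w in _candidate_walks(g) if brute_is_safe(g, w, mode)
    )


def brute_maximal_safe_walks(g: Digraph, mode: str = "node") -> frozenset[Walk]:
    """Safe walks not wrap-around-contained in a safe walk of another class."""
    _guard(g)
    safe = [w for w in _candidate_walks(g) if brute_is_safe(g, w, mode)]
    canon = {w: w.canonical() for w in safe}

    def dominated(w: Walk) -> bool:
        for other in safe:
            if canon[other] == canon[w]:
                continue
            if other.is_circular:
                if CircularWalk(other.nodes).contains_subwalk(w):
                    return True
            else:
                k, kb = w.length, other.length
                if k <= kb and any(
                    other.nodes[i:i + k + 1] == w.nodes
                    for i in range(kb - k + 1)
                ):
                    return True
        return False

    return frozenset(canon[w] for w in safe if not dominated(w))


def brute_min_reconstruction_length(g: Digraph, mode: str = "node") -> int:
    """Minimum total length of a set of simple cycles covering all nodes
    (edges).  Decomposing circular walks into cycles preserves coverage and
    total length, so this equals the minimum over all reconstructions."""
    _guard(g)
    cycles = _cycles(g)
    if len(cycles) > 16:
        raise ValueError("too many cycles for exhaustive covering search")
    targets = set(g.nodes) if mode == "node" else set(g.edges)

    def covered(subset) -> set:
        got = set()
        for c in subset:
            if mode == "node":
                got.update(c[:-1])
            else:
                got.update((c[i], c[i + 1]) for i in range(len(c) - 1))
        return got

    best = None
    for r in range(1, len(cycles) + 1):
        for subset in itertools.combinations(cycles, r):
            total = sum(len(c) - 1 for c in subset)
            if best is not None and total >= best:
                continue
            if covered(subset) >= targets:
                best = total
    if best is None:
        raise ValueError("graph admits no covering set of cycles")
    return best
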