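"""Certificates: the extra condition that separates multi-genome safety from
single-genome safety.

A node x (edge e) is a *certificate* of a walk w when every cycle through x
(through e) contains w as a sub-walk; a walk with a certificate cannot be
avoided by re-covering its nodes with other cycles.  An omnitig is safe for
circular-walk covers precisely when it has at least one certificate.

For single nodes, certificates come from the node-split graph G': removing
x's split edge disconnects y_in from y_out exactly when every cycle through
y passes through x.  For single edges the same test runs on G - e directly.
For a walk, the certificate set is the intersection of its items'
certificate sets, and the emptiness of those intersections along a covering
circular walk is answered in O(1) by an amortized sliding-window counter
structure (:func:`window_scan`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

from .digraph import (
    CircularWalk,
    Digraph,
    Edge,
    Node,
    Walk,
    require_strongly_connected,
    scc_index,
    split_nodes,
)

__all__ = ["CertTable", "node_certificates", "edge_certificates",
           "walk_certificates", "WindowState", "window_scan"]


@dataclass(frozen=True)
class CertTable:
    """Per-item certificate sets over a fixed universe.

    ``mode`` is "node" (universe = nodes, Cert maps nodes to node sets) or
    "edge" (universe = edges).  Always ``item in cert(item)``: everything on
    a cycle certifies itself.
    """

    mode: str
    certs: Mapping = field(hash=False)

    def cert(self, item) -> frozenset:
        return self.certs[item]

    @property
    def universe(self) -> tuple:
        return tuple(sorted(self.certs))


def node_certificates(g: Digraph) -> CertTable:
    """Cert(x) for every node x of a strongly connected graph.

    Cert(x) = {x} plus every y whose split pair (y_in, y_out) falls into
    different strongly connected components of G' minus x's split edge.
    """
    require_strongly_connected(g)
    gp = split_nodes(g).graph
    certs: dict[Node, frozenset[Node]] = {}
    for x in g.nodes:
        comp = scc_index(gp, skip_edge=((x, "in"), (x, "out")))
        members = {x}
        for y in g.nodes:
            if y != x and comp[(y, "in")] != comp[(y, "out")]:
                members.add(y)
        certs[x] = frozenset(members)
    return CertTable("node", certs)


def edge_certificates(g: Digraph) -> CertTable:
    """Cert(e) for every edge e: {e} plus every edge f = (u, v) whose
    endpoints are separated (u unreachable again from v) in G - e.

    Since f itself survives in G - e, u and v share a component there iff
    some cycle through f avoids e.
    """
    require_strongly_connected(g)
    certs: dict[Edge, frozenset[Edge]] = {}
    for e in g.edges:
        comp = scc_index(g, skip_edge=e)
        members = {e}
        for f in g.edges:
            if f != e and comp[f[0]] != comp[f[1]]:
                members.add(f)
        certs[e] = frozenset(members)
    return CertTable("edge", certs)


def walk_certificates(table: CertTable, w: Walk) -> frozenset:
    """Certificate set of a walk: intersection over its nodes (node mode) or
    its edges (edge mode).  Valid for omnitigs that are paths or cycles."""
    items = w.nodes if table.mode == "node" else w.edges
    if not items:
        raise ValueError("edge-mode certificates need a proper walk")
    out = None
    for it in items:
        s = table.certs[it]
        out = s if out is None else out & s
        if not out:
            return frozenset()
    return out


# ---------------------------------------------------------------------------
# Sliding-window intersection along a covering circular walk
# ---------------------------------------------------------------------------


class WindowState:
    """Amortized non-emptiness oracle for windows of certificate sets.

    Along the circular item sequence of C (nodes in node mode, edges in edge
    mode) it precomputes, for every end position j, the widest window ending
    at j (capped at ``max_items``) whose certificate sets have a common
    element.  Counters per candidate certificate plus a histogram of counter
    values make add/remove O(|set|) and the emptiness test O(1); the left
    endpoint only ever advances, so the whole scan is linear in total set
    size.  ``query(i, k)`` then answers in O(1) whether the sets of C(i, k)'s
    items intersect.
    """

    def __init__(self, table: CertTable, cover: CircularWalk, cap: int):
        self.table = table
        self.cover = cover
        self.cap = int(cap)
        if self.cap < 1:
            raise ValueError("cap must be >= 1")
        d = cover.d
        if table.mode == "node":
            seq = [table.certs[cover.node_at(i)] for i in range(d)]
            max_items = self.cap + 1  # a walk of length k touches k+1 nodes
        else:
            seq = [table.certs[cover.edge_at(i)] for i in range(d)]
            max_items = self.cap
        universe = sorted({x for s in seq for x in s})
        index = {x: i for i, x in enumerate(universe)}
        iseq = [tuple(index[x] for x in s) for s in seq]

        cnt = [0] * len(universe)
        hist = [0] * (max_items + 2)
        hist[0] = len(universe)
        size = 0

        def add(j: int) -> None:
            nonlocal size
            for it in iseq[j % d]:
                hist[cnt[it]] -= 1
                cnt[it] += 1
                hist[cnt[it]] += 1
            size += 1

        def remove(j: int) -> None:
            nonlocal size
            for it in iseq[j % d]:
                hist[cnt[it]] -= 1
                cnt[it] -= 1
                hist[cnt[it]] += 1
            size -= 1

        widths = [0] * d
        # seed the window ending at position 0 by scanning left
        add(0)
        left = 0
        while size < max_items:
            add(left - 1)
            if hist[size] == 0:
                remove(left - 1)
                break
            left -= 1
        widths[0] = size
        for j in range(1, d):
            add(j)
            if size > max_items:
                remove(left)
                left += 1
            while size > 1 and hist[size] == 0:
                remove(left)
                left += 1
            widths[j] = size
        self._widths = widths
        self._max_items = max_items

    def query(self, i: int, k: int) -> bool:
        """Non-emptiness of the certificate intersection of C(i, k)."""
        if k > self.cap:
            raise ValueError(f"window query length {k} exceeds cap {self.cap}")
        if k < 0:
            raise ValueError("k must be >= 0")
        d = self.cover.d
        count = k + 1 if self.table.mode == "node" else k
        if count == 0:
            return True
        j = (i + count - 1) % d
        return count <= self._widths[j]


def window_scan(table: CertTable, cover: CircularWalk, cap: int) -> WindowState:
    return WindowState(table, cover, cap)
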