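"""Synthetic assembly graphs: fixtures, random strongly connected digraphs,
and node-centric de Bruijn graphs of simulated circular genomes.

Everything the test-bench needs is generated here, deterministically.  The
de Bruijn construction is single-stranded (no reverse complements) and
node-centric: nodes are k-mers, edges are observed (k+1)-mers, read
circularly, so each circular genome traces a circular walk in its graph --
exactly the covering model the safety analysis assumes.
"""

from __future__ import annotations

import itertools
import random
from typing import Iterable, Iterator, Sequence

from .digraph import Digraph, Node

__all__ = [
    "fixture",
    "random_strongly_connected",
    "de_bruijn_graph",
    "exhaustive_strongly_connected",
]


def fixture(name: str, **params) -> Digraph:
    """Named test graphs.

    - ``cycle`` (n): the directed cycle on nodes 1..n (n == 1: a self-loop).
    - ``bowtie``: two directed triangles sharing the hub node "c"
      (c, a1, a2, c) and (c, b1, b2, c).
    - ``flower`` (p, length): p petal cycles of the given length sharing one
      hub; every covering reconstruction must traverse each petal separately,
      so total cover length grows as p * length.
    - ``chorded_triangle``: triangle 1, 2, 3 with the extra chord (1, 3).
    - ``two_node_cycle``: u <-> v.
    """
    if name == "cycle":
        n = int(params.get("n", 3))
        if n < 1:
            raise ValueError("cycle needs n >= 1")
        return Digraph((i, i % n + 1) for i in range(1, n + 1))
    if name == "bowtie":
        return Digraph([
            ("c", "a1"), ("a1", "a2"), ("a2", "c"),
            ("c", "b1"), ("b1", "b2"), ("b2", "c"),
        ])
    if name == "flower":
        p = int(params.get("p", 2))
        length = int(params.get("length", 3))
        if p < 1 or length < 2:
            raise ValueError("flower needs p >= 1 petals of length >= 2")
        hub = (0, 0)
        edges = []
        for i in range(1, p + 1):
            petal = [hub] + [(i, j) for j in range(1, length)] + [hub]
            edges.extend(zip(petal, petal[1:]))
        return Digraph(edges)
    if name == "chorded_triangle":
        return Digraph([(1, 2), (2, 3), (3, 1), (1, 3)])
    if name == "two_node_cycle":
        return Digraph([(1, 2), (2, 1)])
    raise ValueError(f"unknown fixture {name!r}")


def random_strongly_connected(n: int, extra_edges: int = 0, seed: int = 0) -> Digraph:
    """Random strongly connected digraph: a random Hamiltonian backbone cycle
    on nodes 1..n plus ``extra_edges`` distinct random non-loop edges.

    Deterministic per seed.  Capacity for extras is n^2 - 2n (all ordered
    non-loop pairs minus the backbone).  n == 1 yields the single node with
    its self-loop.
    """
    if n < 1:
        raise ValueError("n >= 1 required")
    rng = random.Random(seed)
    nodes = list(range(1, n + 1))
    order = nodes[:]
    rng.shuffle(order)
    backbone = {
        (order[i], order[(i + 1) % n]) for i in range(n)
    } if n > 1 else {(1, 1)}
    pool = sorted(
        (u, v)
        for u in nodes for v in nodes
        if u != v and (u, v) not in backbone
    )
    if extra_edges > len(pool):
        raise ValueError(
            f"extra_edges={extra_edges} exceeds capacity {len(pool)}"
        )
    extras = rng.sample(pool, extra_edges)
    return Digraph(backbone | set(extras))


def de_bruijn_graph(genomes: Sequence[str], k: int) -> Digraph:
    """Node-centric de Bruijn graph of circular genomes.

    Nodes are the distinct k-mers read circularly from the genomes; there is
    an edge (a, b) whenever some genome contains the (k + 1)-mer a + b[-1]
    circularly.  Parallel observations collapse (the graph is simple).
    """
    if k < 1:
        raise ValueError("k >= 1 required")
    edges = set()
    nodes = set()
    for s in genomes:
        if len(s) < k:
            raise ValueError(f"genome shorter than k: {s!r}")
        doubled = s + s
        for i in range(len(s)):
            a = doubled[i:i + k]
            b = doubled[i + 1:i + 1 + k]
            nodes.update((a, b))
            edges.add((a, b))
    return Digraph(edges, nodes)


def exhaustive_strongly_connected(
    n: int, self_loops: bool = True
) -> Iterator[Digraph]:
    """Every strongly connected digraph on the labelled nodes 1..n,
    enumerated over all edge subsets.  Feasible for n <= 4."""
    if n > 4:
        raise ValueError("exhaustive enumeration is limited to n <= 4")
    nodes = list(range(1, n + 1))
    all_edges = [
        (u, v) for u in nodes for v in nodes if self_loops or u != v
    ]
    for r in range(1, len(all_edges) + 1):
        for es in itertools.combinations(all_edges, r):
            g = Digraph(es, nodes)
            if g.is_strongly_connected():
                yield g
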