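"""Maximal safe walks, explicit and duplicate-free.

A safe walk is worth reporting only if it is not contained in a longer safe
walk (with wrap-around containment for cycles).  Maximality is decided on
the covering walk C: a safe walk class of length k is *extended* when some
occurrence of it in C is the body of a safe walk of length k + 1 (one
position to the left or starting at the same index).  Classes never extended
are maximal.  Two corrections to that occurrence-local rule are needed:

* rotations of one safe cycle are a single class (they contain each other
  with wrap-around), keyed by the lexicographically smallest rotation;
* a safe path may sit inside a safe *cycle* only via wrap-around, invisible
  to per-occurrence extension; since safe cycles are always maximal, a final
  filter drops paths wrap-contained in an output cycle.

Occurrence classes are grouped by exact walk identity (a hash index over the
sub-walks of C); any structure meeting this contract would do.
"""

from __future__ import annotations

from collections import defaultdict

from .digraph import CircularWalk, Walk
from .safewalks import SafePairs

__all__ = ["OccurrenceIndex", "walk_extension_flags", "maximal_safe_walks"]


class OccurrenceIndex:
    """Occurrence classes of safe sub-walks of one length k.

    Two pairs (i, k) and (j, k) belong to the same class iff C(i, k) and
    C(j, k) are the same walk; safe rotations of one cycle share a class.
    """

    def __init__(self, pairs: SafePairs, k: int):
        self.k = k
        self.classes: dict[Walk, list[int]] = defaultdict(list)
        for i in sorted(pairs.S(k)):
            self.classes[pairs.walk(i, k).canonical()].append(i)

    def occurrences(self, walk: Walk) -> list[int]:
        return self.classes[walk.canonical()]


def walk_extension_flags(pairs: SafePairs, k: int) -> dict[Walk, bool]:
    """For every safe walk class of length k: was any occurrence extended
    into a safe walk of length k + 1?"""
    d = pairs.cover.d
    nxt = pairs.S(k + 1) if k + 1 <= pairs.cap else frozenset()
    index = OccurrenceIndex(pairs, k)
    return {
        w: any(i in nxt or (i - 1) % d in nxt for i in occ)
        for w, occ in index.classes.items()
    }


def _wrap_contained(w: Walk, cycle_walk: Walk) -> bool:
    return CircularWalk(cycle_walk.nodes).contains_subwalk(w)


def maximal_safe_walks(pairs: SafePairs) -> list[Walk]:
    """Every safe walk that is not a sub-walk (wrap-around for cycles) of
    another safe walk; no duplicates; cycles canonicalized; ordered by
    length descending, then lexicographically."""
    candidates: list[Walk] = []
    for k in range(1, pairs.cap + 1):
        if not pairs.S(k):
            continue
        for w, extended in walk_extension_flags(pairs, k).items():
            if not extended:
                candidates.append(w)
    cycles = [w for w in candidates if w.is_cycle]
    out = [
        w for w in candidates
        if w.is_cycle or not any(_wrap_contained(w, c) for c in cycles)
    ]
    out.sort(key=lambda w: (-w.length, w.nodes))
    return out
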