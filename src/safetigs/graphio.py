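"""Reading and writing assembly graphs and genomes.

Two plain-text graph formats are supported:

* **edgelist** -- one ``tail<TAB>head`` pair per line, ``#`` comments;
* **GFA1** (forward-orientation subset) -- ``S`` lines become nodes, ``L``
  lines with ``+ +`` orientations become directed edges.  Reverse-complement
  (``-``) orientations are out of scope and rejected.

Node identifiers read from files are strings.  Circular genomes for the
de Bruijn generator come from FASTA; a record is treated as circular when its
description carries a ``circular=true`` tag.
"""

from __future__ import annotations

import io
import sys
from typing import Iterable, TextIO

from Bio import SeqIO

from .digraph import Digraph

__all__ = ["read_graph", "write_graph", "read_circular_genomes",
           "GraphFormatError"]


class GraphFormatError(ValueError):
    """Parse error, carrying the offending line number."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)


def _read_edgelist(handle: TextIO) -> Digraph:
    edges = []
    nodes = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) == 1:
            parts = line.split()
        if len(parts) == 1:
            # a bare token declares an isolated node
            nodes.append(parts[0])
            continue
        if len(parts) != 2:
            raise GraphFormatError(
                f"expected 'tail<TAB>head', got {line!r}", lineno
            )
        edges.append((parts[0], parts[1]))
    return Digraph(edges, nodes)


def _read_gfa1(handle: TextIO) -> Digraph:
    nodes = []
    edges = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        fields = line.split("\t")
        tag = fields[0]
        if tag == "H":
            continue
        if tag == "S":
            if len(fields) < 2:
                raise GraphFormatError("S line needs a segment name", lineno)
            nodes.append(fields[1])
        elif tag == "L":
            if len(fields) < 5:
                raise GraphFormatError(
                    "L line needs from, from_orient, to, to_orient", lineno
                )
            a, ao, b, bo = fields[1:5]
            if ao != "+" or bo != "+":
                raise GraphFormatError(
                    "only forward (+/+) link orientations are supported "
                    "(reverse complements are out of scope)", lineno
                )
            edges.append((a, b))
        # other record types (P, C, ...) are ignored
    return Digraph(edges, nodes)


def read_graph(source, fmt: str = "edgelist") -> Digraph:
    """Read a graph from a path, file object, or string content."""
    if hasattr(source, "read"):
        handle = source
        close = False
    else:
        text = str(source)
        if "\n" in text or "\t" in text:
            handle = io.StringIO(text)
            close = False
        else:
            handle = open(text, "r", encoding="utf-8")
            close = True
    try:
        if fmt == "edgelist":
            return _read_edgelist(handle)
        if fmt == "gfa1":
            return _read_gfa1(handle)
        raise ValueError(f"unknown graph format {fmt!r}")
    finally:
        if close:
            handle.close()


def write_graph(g: Digraph, handle: TextIO | None = None, fmt: str = "edgelist") -> str:
    """Serialize a graph; returns the text and optionally writes it."""
    lines = []
    if fmt == "edgelist":
        with_edges = {u for u, _ in g.edges} | {v for _, v in g.edges}
        for v in g.nodes:
            if v not in with_edges:
                lines.append(str(v))
        for u, v in g.edges:
            lines.append(f"{u}\t{v}")
    elif fmt == "gfa1":
        lines.append("H\tVN:Z:1.0")
        for v in g.nodes:
            lines.append(f"S\t{v}\t*")
        for u, v in g.edges:
            lines.append(f"L\t{u}\t+\t{v}\t+\t0M")
    else:
        raise ValueError(f"unknown graph format {fmt!r}")
    text = "\n".join(lines) + "\n"
    if handle is not None:
        handle.write(text)
    return text


def read_circular_genomes(source) -> list[str]:
    """Circular genome sequences from FASTA (records tagged circular=true)."""
    if hasattr(source, "read"):
        handle = source
    else:
        handle = open(source, "r", encoding="utf-8")
    genomes = []
    for rec in SeqIO.parse(handle, "fasta"):
        if "circular=true" in rec.description:
            genomes.append(str(rec.seq))
    return genomes
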