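# safetigs

**Safe and complete contig extraction from circular-walk covers of assembly
graphs.**

## The problem

Metagenomic assembly asks for the circular genomes of *all* bacteria in a
sample.  On an assembly graph *G* (for example a node-centric de Bruijn
graph) this is naturally modelled as finding a **collection of circular
walks that together cover every node** (or every edge) of *G* — each walk a
circular genome, the cover condition saying that together they explain all
reads.  Real graphs admit many such collections, so an assembler should only
report walks that occur in **every** solution.  Such walks are called
**safe**; an algorithm reporting *all* of them is **complete**.  Safe walks
generalize unitigs (maximal paths with degree-one internal nodes), which are
what classical assemblers report.

`safetigs` computes, for a strongly connected directed graph (self-loops
allowed, no parallel edges):

* all node-safe and all edge-safe walks, encoded as sub-walks `C(i, k)` of a
  covering circular walk `C`;
* the **maximal** safe walks — the contigs worth reporting — explicitly and
  without duplicates;
* minimum-total-length covering reconstructions via an exact minimum-cost
  circulation;
* a brute-force reference implementation (exhaustive cycle and path
  enumeration) used as ground truth throughout the test suite.

## The characterization and the algorithm

A walk `w = (v0, e0, v1, …, vt, et, vt+1)` is **node-safe** iff

1. **`w` is an omnitig** — there is no proper `vj`–`vi` path (`1 ≤ i ≤ j ≤ t`)
   whose first edge differs from `ej` and whose last edge differs from
   `e(i−1)`, and each `ej` is the only `vj`–`v(j+1)` path — *and*
2. **`w` has a certificate** — some node `x` such that every cycle through
   `x` contains `w` as a sub-walk.  Writing `Cert(x)` for the nodes `x`
   certifies, condition 2 is `Cert(v0) ∩ … ∩ Cert(vt+1) ≠ ∅`.

Edge-safety is the same with condition 1's only-path clause dropped and
certificates taken over edges; it equals node-safety in the subdivision
graph `S(G)`.

The algorithm builds one node-covering circular walk `C` (length
`n ≤ d ≤ n²`), then marks every safe `C(i, k)` by dynamic programming on
`k`: a length-`k` sub-walk is safe iff its two length-`(k−1)` sub-walks are,
one constant-time path query finds no bypass, the certificate window
`Cert(v_i) ∩ … ∩ Cert(v_{i+k})` is non-empty (an amortized sliding-window
counter answers this in O(1)), and the sub-walk is a path or a cycle.
Certificates of single nodes come from strongly-connected-component
recomputations in the node-split graph `G′`; the only-path test is a strong
bridge check.  Every safe walk is a sub-walk of `C`, so the scan is
complete.

## Worked example

Two circular genomes sharing a repeat node (the "bowtie": triangles
`c,a1,a2` and `c,b1,b2` joined at `c`):

```python
from safetigs import fixture, node_safe_pairs, enumerate_safe_walks, maximal_safe_walks

g = fixture("bowtie")
pairs = node_safe_pairs(g)
print(len(enumerate_safe_walks(pairs)))      # 12 distinct node-safe walks
for w in maximal_safe_walks(pairs):
    print(w)
```

prints

```
12
a1,a2,c,a1
b1,b2,c,b1
```

Each triangle is reported in full (as a canonical cycle rotation): every
covering collection must traverse it.  The crossing walk `a2,c,b1` is *not*
reported, although it is an omnitig: each triangle can be covered by its own
cycle, so no node certifies the crossing — reporting it would risk a
chimeric contig joining two genomes.  The same computation from the shell:

```bash
safetigs gen fixture bowtie | safetigs maximal --mode node
```

See `examples/` for more: edge-mode safety and the subdivision reduction,
contigs of a simulated plasmid mixture, minimum-length reconstructions, and
the brute-force cross-check.

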