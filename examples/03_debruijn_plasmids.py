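"""Maximal safe contigs from a simulated plasmid mixture.

Three random circular plasmids share a 12 bp cassette.  Their joint
node-centric de Bruijn graph (k = 6) merges at the cassette k-mers, and the
maximal safe walks are exactly the fragments any assembler may report
without risking a mis-assembly, no matter which combination of circular
genomes actually produced the reads.
"""

import random

from safetigs import de_bruijn_graph, maximal_safe_walks, safe_walks_per_component

rng = random.Random(42)
cassette = "".join(rng.choice("ACGT") for _ in range(12))
plasmids = [cassette + "".join(rng.choice("ACGT") for _ in range(48))
            for _ in range(3)]

print("shared cassette:", cassette)
for i, p in enumerate(plasmids):
    print(f"plasmid {i + 1} ({len(p)} bp, circular): {p[:30]}...")

g = de_bruijn_graph(plasmids, k=6)
print(f"\nde Bruijn graph: {g.n} k-mers, {g.m} edges")

walks = [w for pairs in safe_walks_per_component(g, "node")
         for w in maximal_safe_walks(pairs)]
walks.sort(key=lambda w: -w.length)
print(f"{len(walks)} maximal node-safe walks; lengths:",
      [w.length for w in walks])

# spell the longest contig back into sequence: first k-mer + last bases
w = walks[0]
seq = w.nodes[0] + "".join(km[-1] for km in w.nodes[1:])
print(f"\nlongest safe contig ({w.length} edges) spells: {seq[:40]}...")
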