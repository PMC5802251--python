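"""Minimum-total-length covering reconstructions via min-cost circulation.

Instead of scanning one (possibly wasteful) covering walk, the scan can
start from a covering collection of cycles of minimum total length.  The
flower graph -- p petal cycles sharing a hub -- shows why the optimum needs
one walk per petal.
"""

from safetigs import fixture, min_length_reconstruction, node_covering_circular_walk

for p in (2, 3, 4):
    g = fixture("flower", p=p, length=3)
    single = node_covering_circular_walk(g)
    rec = min_length_reconstruction(g, "node")
    print(f"flower(p={p}, L=3): n={g.n}")
    print(f"  single covering walk length: {single.d}")
    print(f"  min reconstruction: {len(rec.walks)} cycles, "
          f"total length {rec.total_length}")
    for w in rec.walks:
        print(f"    {w}")
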