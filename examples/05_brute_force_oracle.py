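"""Cross-checking the scan against the brute-force characterization.

On tiny graphs, safety can be decided by enumerating every simple cycle and
every constrained path.  This independent route must agree exactly with the
efficient scan -- here on all strongly connected 3-node digraphs.
"""

from safetigs import edge_safe_pairs, enumerate_safe_walks, node_safe_pairs
from safetigs.oracle import brute_all_safe_walks
from safetigs.synthetic import exhaustive_strongly_connected

graphs = mismatches = 0
for g in exhaustive_strongly_connected(3):
    graphs += 1
    for mode, make in (("node", node_safe_pairs), ("edge", edge_safe_pairs)):
        if enumerate_safe_walks(make(g)) != brute_all_safe_walks(g, mode):
            mismatches += 1
            print("MISMATCH:", mode, g.edges)

print(f"checked {graphs} strongly connected 3-node graphs in both modes: "
      f"{mismatches} mismatches")
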