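"""Edge-covering safety and its reduction to node-covering safety.

In the edge-covering model every *edge* must be explained by some circular
walk, so every single edge is automatically safe (it certifies itself).
Edge-safety reduces to node-safety on the subdivision graph S(G), where
every edge gets a mid-point node; this example verifies the correspondence
on the chorded triangle.
"""

from safetigs import (
    edge_safe_pairs,
    enumerate_safe_walks,
    fixture,
    node_safe_pairs,
    subdivide_edges,
)

g = fixture("chorded_triangle")
print(f"chorded triangle edges: {g.edges}")

edge_side = enumerate_safe_walks(edge_safe_pairs(g))
print(f"\n{len(edge_side)} distinct edge-safe walks:")
for w in sorted(edge_side, key=lambda w: (-w.length, str(w.nodes))):
    print(f"  {w}")

sd = subdivide_edges(g)
node_side = enumerate_safe_walks(node_safe_pairs(sd.graph))
lifted = {sd.lift(w).canonical() for w in edge_side}
print(f"\nS(G) has {sd.graph.n} nodes and {sd.graph.m} edges; "
      f"{len(node_side)} node-safe walks")
print("every edge-safe walk lifts to a node-safe walk of S(G):",
      lifted <= node_side)
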