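# Methods

## Model

The input is a directed graph `G` with `n` nodes and `m` edges, no parallel
edges, self-loops permitted.  A *covering reconstruction* is a collection of
circular walks whose union covers every node (node mode) or every edge
(edge mode); it models the set of circular bacterial genomes jointly
explaining all reads of a metagenomic sample.  A walk is *safe* when every
covering reconstruction contains it as a sub-walk of one of its walks
(wrap-around containment inside circular walks, defined only when the
sub-walk is no longer than the circular walk).  Covering walks cannot leave
strongly connected components, so the core routines require strongly
connected inputs; `safe_walks_per_component` handles general graphs (node
mode: every node must lie on a cycle; edge mode: the graph must be a
disjoint union of strongly connected graphs).

Safety is decided through a two-part characterization: the walk must be an
omnitig (no bypassing path, and — in node mode — each of its edges the only
path between its endpoints), and it must have a *certificate*: a node
(edge) all of whose cycles contain the walk.  The certificate clause is
what separates the multi-genome model from the single-genome one: an
omnitig crossing a shared repeat has no certificate, because each side of
the repeat can be covered separately.

## Algorithm

`node_safe_pairs` / `edge_safe_pairs` build one covering circular walk `C`
by visiting targets in sorted order and stitching BFS shortest paths
(`n ≤ d ≤ n²` in node mode, `d ≤ mn` in edge mode), then mark all safe
sub-walks `C(i, k)` by induction on `k`:

* `k = 1`: node mode requires the edge to be the only path between its
  endpoints (strong-bridge test) and `Cert(v_i) ∩ Cert(v_{i+1}) ≠ ∅`; in
  edge mode every single edge is safe (it certifies itself).
* `k > 1`: `i` and `i+1 (mod d)` must be marked at `k−1`; one path query
  must find no bypass (the omnitig gluing property); the certificate window
  must be non-empty; and `C(i, k)` must be a path or a cycle.

Safe walks are sub-walks of every covering walk, hence of `C`, so the scan
is complete; lengths are capped at `n` because safe walks are paths or
cycles.

**Certificates.**  `Cert(x)` is computed on the node-split graph `G′`
(each `x` becomes `x_in → x_out`): `y ∈ Cert(x)` iff removing `x`'s split
edge separates `y_in` from `y_out`.  Edge certificates run the same test on
`G − e` directly.  Both use an iterative Tarjan SCC routine with a
*skip-edge* parameter, so the per-item recomputation never copies the
graph.  A walk's certificate set is the intersection over its nodes
(edges); this identity holds for omnitigs that are paths or cycles, which
is the only place the scan uses it (see "Path-or-cycle guard").

**Certificate windows.**  Non-emptiness of
`Cert(v_i) ∩ … ∩ Cert(v_{i+k})` along `C` is answered in O(1) from a
precomputed per-endpoint maximal window width.  The window keeps one
counter per candidate certificate plus a histogram of counter values, so
"some candidate present in all sets of the window" is a single histogram
lookup; the left endpoint only advances, giving a linear amortized scan.
Window width is capped at `cap + 1` items (node mode; `cap = n`), and a
window may wrap past `d` (duplicate positions are counted twice, which
leaves the intersection unchanged).

**Path queries.**  The omnitig gluing step asks: is there a proper
`u`–`z` path with first edge ≠ `e1` and last edge ≠ `e2` (a `u`–`u` "path"
meaning a cycle through `u`)?  A simple `u`–`z` path ending with edge
`(q, z)` exists iff `q` is an in-neighbour of `z` reachable from `u`
without passing through `z`; the table therefore caches, per
`(e1, target z)`, the set of in-neighbours of `z` reachable from `u` in
`G − e1` with `z` deleted (not deleted when `z = u`, since a simple path
never revisits its source).  One BFS per cached row, O(1) per query, exact
under simple-path semantics — validated exhaustively against enumeration on
all ≤4-node strongly connected digraphs, diagonal `e1 = e2` included.  An
alternative single-BFS-per-edge counting scheme (reachable in-neighbour
counts without deleting `z`) answers *walk* existence instead of path
existence; the two differ as soon as every witness path is forced through
`z` twice, so this package uses the per-target form.  End-to-end safe-walk
output is identical under both forms on the exhaustive ≤4-node family; the
per-target form additionally matches the path-semantics contract of the
query itself.

**Path-or-cycle guard.**  Every marked `C(i, k)` is required to have
distinct nodes (allowing first = last).  Safe walks are always paths or
cycles, so the guard never removes a safe walk.  It is load-bearing in edge
mode: without it, a walk such as `(1,2,1,2)` in the graph
`{(1,2),(2,1),(2,3),(3,1)}` passes the incremental omnitig checks and has a
non-empty *intersection* of edge certificates, yet fits in no simple cycle
and is therefore unsafe — the walk-level certificate identity fails for
omnitigs with repeated edges.  With the guard, the scan agrees with the
brute-force characterization on every strongly connected digraph with ≤ 4
nodes (25 845 graphs, both modes, exhaustive) and on seeded random graphs
with ≤ 8 nodes.

**Self-loops.**  Removing a self-loop never changes the SCC partition, so
the strong-bridge recount cannot decide whether a loop is the only cycle
through its node.  The only-path predicate treats loops separately: loop
`(v, v)` is the only `v`–`v` path iff `v`'s component in `G − loop` is
trivial.  This matters exactly for the single-node graph, whose loop is
safe.

**Maximal walks.**  A safe walk class of length `k` (classes group
identical sub-walks; safe rotations of one cycle share a class keyed by the
lexicographically smallest rotation) is maximal when no occurrence in `C`
extends to a marked walk of length `k + 1` on either side.  Safety is *not*
rotation-invariant — `(2,1,2)` can be safe while `(1,2,1)` is not — so
occurrences are tracked per exact walk and only collapsed for output.  One
correction to the occurrence-local rule: a safe path can sit inside a safe
cycle only via wrap-around, which no occurrence extension sees; since safe
cycles are always maximal and nothing else can dominate by wrap-around, a
final filter removes paths wrap-contained in an output cycle.  The
occurrence index is an exact hash grouping of sub-walks; no suffix
structure is needed at the problem sizes this package targets.

**Minimum-length reconstructions.**  A covering collection of cycles of
minimum total length comes from an exact minimum-cost circulation: in node
mode on `G′` with demand 1 / cost 0 on split edges and demand 0 / cost 1 on
original edges, in edge mode on `G` with demand 1 / cost 1 per edge.  Lower
bounds are removed by the standard forced-flow transformation and the
residual solved with networkx's network simplex (exact on integers);
self-loops carry exactly their forced flow.  The integral circulation is
decomposed deterministically: repeatedly walk positive-flow edges from the
smallest node with remaining out-flow, always choosing the smallest
successor, and cancel the first cycle closed.

## Brute-force oracle

The reference implementation decides the characterization literally: all
simple cycles (networkx), all constrained simple paths, certificates by
cycle containment, candidates being every wrap-around sub-walk of every
simple cycle (complete, because a safe walk needs a certificate and hence
fits in a cycle).  It shares no code with the scan beyond the graph
container and is guarded to ≤ 12 nodes.  The brute minimum reconstruction
enumerates subsets of simple cycles, valid because decomposing circular
walks into cycles preserves coverage and total length.

## Synthetic data

* `fixture` — cycle, bowtie (two triangles sharing a hub), flower(p, L)
  (p petal cycles sharing a hub; any covering reconstruction costs p·L,
  so total cover length grows quadratically when p and L grow with n),
  chorded triangle, two-node cycle.
* `random_strongly_connected(n, extra, seed)` — a random Hamiltonian
  backbone cycle plus `extra` distinct non-loop edges; strongly connected
  by construction, deterministic per seed.
* `de_bruijn_graph(genomes, k)` — node-centric, single-stranded, circular
  reads; no reverse complements, no sequencing errors or coverage model.
  Consequently, passing tests speak to the combinatorial model — graphs
  whose circular genomes exactly cover the nodes/edges — not to noisy real
  data, where error edges and strand ambiguity would first have to be
  cleaned away.
* `exhaustive_strongly_connected(n)` — every strongly connected digraph on
  ≤ 4 labelled nodes, self-loops included.

## Problem sizes and numerical choices

The test suite compares scan vs. brute force exhaustively on all 25 845
strongly connected digraphs with ≤ 4 nodes and on 200 seeded random graphs
with ≤ 8 nodes, validates the path-query table and certificate windows
against direct recomputation on the same families, and checks the
closed-form answer on cycle graphs with n ≤ 10 (all n² pairs safe, one
maximal canonical cycle).  The scaling smoke test times the scan on random
graphs with n ∈ {50, 100, 200} at density m = 3n and requires a log–log
slope ≤ 3.5 (measured ≈ 2).  All arithmetic is integral; there are no
tolerances.  Ties everywhere (BFS successors, cycle extraction, output
order) break by sorted node identity, so byte-identical reruns are
guaranteed.  Node identifiers must be mutually sortable within one graph;
identifiers read from files are strings.

## Known limitations

* Strong bridges are found by per-edge SCC recount (O(m·(n+m))), not by a
  linear-time algorithm; certificates and the per-target path-query rows
  likewise favour simplicity over the best known asymptotics.  At the
  problem sizes above the scan is sub-second; n in the thousands is fine,
  far beyond that the quadratic table and window preprocessing dominate.
* Single-stranded model: reverse complements, linear chromosomes, fixed
  genome counts, and sequencing errors are out of scope.
* The GFA1 reader supports the forward-orientation subset only (S lines and
  `+ +` L lines) and rejects `-` orientations.
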