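# Methods

## Problem and model

The package treats pathway reconstruction as a ranked-enumeration problem:
in a directed network *G* whose edges may carry non-negative weights, find
the *k* best-scoring **loopless** paths (each node visited at most once)
that start at some member of a source set *S* and end at some member of a
target set *T*. The biological reading is receptors → transcription
factors through a background interactome whose edge weights encode
experimental reliability, but nothing in the machinery is specific to that
reading.

Set-to-set search reduces to single-pair search via a super source *s\**
with zero-cost edges to every source and a super target *t\** with
zero-cost edges from every target. Super edges cost exactly 0 in every
weight mode, so they never influence costs, scores, or ranking; they are
stripped from all reported paths.

## Cost transform

Every search minimises a non-negative additive cost per edge:

* unweighted: cost 1 per edge; the score of a path is its edge count.
* additive: cost = weight + penalty; score = sum of raw weights.
* probability: weights are reliabilities in (0, 1]; cost =
  |log w| + log(penalty); score = product of raw weights. Minimising the
  summed cost maximises the product, and with penalty 1 the mapping is an
  order isomorphism.

Decisions that were genuinely open:

* **Natural logarithm.** Ranking is invariant to the base and the reported
  score is the raw product, so the choice is externally unobservable; it is
  fixed here so internal cost values are reproducible.
* **Scores exclude the penalty.** The penalty is a ranking device — a
  per-edge surcharge discouraging long paths — not part of the path's
  meaning. Ranking uses the penalised cost; the table shows the raw score.
  Consequently, with a penalty other than the identity (1 for probability,
  0 for additive) reported scores need not be monotone in rank.
* **Domain checks.** Probability weights of exactly 0 are rejected up
  front (infinite cost), as are weights > 1 and negative additive weights
  (Dijkstra/A\* require non-negative costs). An invalid user k or penalty
  falls back to the documented default (k = 200; penalty 1/0 by mode) with
  a logged warning rather than aborting.

## Search engine

`reverse_dijkstra` computes every node's distance **to** the anchor by
traversing in-edges outward from it; the graph is never materially
reversed. `astar_shortest_path` is a single-pair A\* that degrades to
Dijkstra without a heuristic. `yen_ksp` implements Yen's algorithm: for
each spur position *j* of the last accepted path, it hides the nodes of
the root prefix (all but the spur node) and the *j→j+1* edge of every
accepted path sharing that root prefix, finds the best spur→anchor path,
and pools the concatenated candidate. Hiding root-prefix nodes is what
makes every output path loopless by construction.

Numerical and determinism choices:

* **One global total order** on paths — (cost, edge count, lexicographic
  node sequence) — is used by the A\* priority queue, Yen's candidate
  pool, and the brute-force oracle. Node identifiers are mapped to integer
  indices in sorted-identifier order so integer tuple comparison equals
  identifier comparison. Heap entries carry the full path tuple; the order
  is extension-monotone, so settle-on-first-pop search returns the unique
  minimum under it, with or without the heuristic.
* **Exact float comparison, no epsilon.** Candidate costs are accumulated
  strictly left-to-right along the full path, so the float value of a
  path's cost is identical regardless of where Yen spurred it — which is
  what makes exact equality against the oracle meaningful.
* **Heuristic reuse.** The distance-to-*t\** map is computed once on the
  full graph before Yen starts. Hiding elements only removes options, so
  these distances remain admissible and consistent lower bounds for every
  spur search; nodes with infinite heuristic are pruned immediately, which
  is where the large-k speed comes from. Recomputing per spur would be
  correct but pointless.
* **Hidden sets, not deletion.** Temporary removals are O(1) set inserts
  that every traversal consults; the engine asserts the sets are empty on
  entry and restores them on exit, so hiding never leaks across calls.
* **Candidate de-duplication** is by node sequence; a candidate seen once
  is never pooled again.

## Pipeline semantics

Endpoints absent from the network are skipped with one warning each
(strict mode aborts instead); if no source or no target survives, the run
fails. Unless sources and targets are allowed inside paths, edges into
sources and out of targets are removed before the search, so a source can
only open and a target only close a path. When a node is both a source
and a target, both rules apply independently.

A node in *S* ∩ *T* admits the degenerate hop *s\*→v→t\** containing no
real edge. These are filtered from the output — a single self-connected
node therefore yields zero paths, since a loopless path cannot return to
its start — and the engine is asked for |S ∩ T| extra paths so the user
still receives k real ones.

The sub-network is exactly the union of the returned paths' nodes and
edges, each annotated with the smallest rank of a path containing it and
carrying its original weight — the attributes a hierarchical renderer
needs, while rendering itself stays out of scope.

## Through-node baseline

`strongest_paths` implements the eight-step through-node procedure used by
simpler connection tools, as a comparison point: forward Dijkstra from
*s\**, reverse-traversal Dijkstra from *t\**, d(v) = the cost of the best
source→target path through v, and emission of π_v for every v with
d(v) ≤ a + τ (a = min d(v)), sorted by (d(v), node id). Two properties are
demonstrated in the tests: at τ = 0 every emitted path is a globally
shortest source→target path, and because at most one path is kept per node
the procedure can miss within-slack paths whenever there are more of them
than nodes — the k-shortest-paths engine has no such cap. If the forward
and backward half-paths at v share an interior node, the concatenation
would contain a loop; that v's path is discarded with a warning (the
procedure's description leaves the junction case open).

## Synthetic data and oracle

The generator samples Erdős–Rényi-style directed graphs (per-pair
probability, or an exact edge count drawn without replacement), no
self-loops, isolated nodes permitted. Weights are uniform in (0, 1] for
probability mode and (0, 10] for additive mode, rounded to six decimals so
written fixtures are byte-stable across platforms (a weight rounding to 0
is bumped to 1e-6 to stay in-domain). Identical spec and seed give
identical networks.

The oracle enumerates **all** loopless origin→anchor paths depth-first,
applying the same cost transform and the same global tie order as the
engine, so engine-vs-oracle comparisons are exact. Enumeration is
exponential and guarded to ≤ 12 nodes.

What the generator does *not* emulate: scale-free degree distributions,
edge-weight correlation with node degree, or any biological topology.
Passing tests therefore certify the algorithmic guarantees (optimality,
order, gap property, endpoint semantics) on adversarially random graphs,
not the biological plausibility of reconstructions on real interactomes.

## Problem sizes used in the checks

The verification battery runs 200 instances (4–10 nodes, edge
probabilities 0.2/0.4/0.6, all three weight modes) for oracle equivalence
and the gap guarantee. On instances with at most 150 loopless paths the
engine is run to exhaustion and compared to the full enumeration; denser
instances — which can hold tens of thousands of loopless paths — are
compared on the first 150, plus explicit prefix checks at smaller k. The
scale run uses 2,000 nodes, 20,000 reliability-weighted edges, 5 sources,
5 targets and k = 1,000, with its leading costs cross-checked against an
independent simple-path enumeration.

## Known limitations

* Pure-Python engine: throughput is ample for k in the thousands on
  10^4–10^5-edge networks, but no attempt is made at parallelism or at
  Eppstein-style algorithms for paths with loops.
* Mixed weighted/unweighted networks are rejected rather than imputed.
* The loader's duplicate-edge rule (keep the maximum weight) favours the
  strongest evidence; users wanting a different aggregation should
  pre-process their edge list.
* Undirected input is handled only via the explicit bidirection flag;
  there is no inference of edge direction.
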