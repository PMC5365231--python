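# pathrank

Reconstruct signaling pathways — or any source→target connection structure —
as the **k best-scoring loopless paths** in a weighted directed interaction
network.

Manually curated pathway databases lag far behind the interactome. Given a
background network *G* of physical and regulatory interactions, a set *S* of
sources (typically receptors) and a set *T* of targets (typically
transcription factors), `pathrank` computes the *k* highest-scoring loopless
paths from any source to any target and assembles them into a ranked path
table plus an annotated sub-network — a candidate reconstruction of the
pathway that connects *S* to *T*, with every node and edge labelled by the
rank of the first path that contains it.

## The algorithm

Set-to-set search is reduced to single-pair search by attaching a super
source *s\** (zero-cost edges to every source) and super target *t\**
(zero-cost edges from every target). The *k* shortest loopless *s\*→t\**
paths are computed with **Yen's algorithm** accelerated by an **A\***
heuristic: the exact distance-to-*t\** of every node, obtained once by a
Dijkstra sweep that traverses edges target-to-source (the graph is never
reversed), is an admissible and consistent lower bound for every spur
search, because Yen's temporary removals — maintained as a set of *hidden*
edges and nodes the traversals ignore — can only lengthen true distances.

Edge weights are interpreted by mode:

| mode          | internal edge cost            | path score (reported)    |
|---------------|-------------------------------|--------------------------|
| `unweighted`  | 1                             | number of edges (min)    |
| `additive`    | w + penalty                   | Σ w (min)                |
| `probability` | \|log w\| + log(penalty)      | Π w (max)                |

Probability weights are edge reliabilities in (0, 1]; minimising summed
\|log\| cost maximises the product of reliabilities. The *edge penalty*
(default 1 for probability weights, 0 otherwise) surcharges every edge,
trading path probability against path length; reported scores always
exclude it. The ranked output carries a guarantee Yen's algorithm provides:
no source→target loopless path has cost strictly between the costs of two
consecutively returned paths. With k = 1 the method reduces to plain
Dijkstra on the augmented graph.

By default, incoming edges of sources and outgoing edges of targets are
removed before the search so endpoints can only open or close a path;
`--allow-st-in-paths` keeps them, and `--targets-are-sources` connects a
single node set to itself.

## Worked example

A five-edge reliability-weighted toy network:

```sh
printf 's\ta\t0.5\na\tt\t0.5\ns\tb\t0.9\nb\tt\t0.9\na\tb\t0.7\n' > toy.tsv
pathrank run --network toy.tsv --sources "s" --targets "t" \
    --weight-type probability -k 5 --out-prefix toy
```

`toy.paths.tsv` — one row per path, best first; the score is the product of
the edge reliabilities along the path:

```
rank	score	path
1	0.81	s|b|t
2	0.315	s|a|b|t
3	0.25	s|a|t
```

Only three loopless s→t paths exist, so asking for five returns three. The
direct s→b→t route (0.9 × 0.9 = 0.81) beats both routes through the less
reliable s→a edge. `toy.subnet.nodes.tsv` annotates each node with the rank
of the first path containing it — node `a` first appears in path 2:

```
node	node_first_path_index
b	1
s	1
t	1
a	2
```

and `toy.subnet.edges.tsv` does the same per edge, keeping original
weights, which is exactly what a renderer needs to lay the reconstruction
out tier by tier.

The same library surface is available programmatically:

```python
from pathrank import CostConfig, Network, PathQuery, reconstruct_pathways

net = Network({"s", "a", "b", "t"},
              {("s", "a"): 0.5, ("a", "t"): 0.5,
               ("s", "b"): 0.9, ("b", "t"): 0.9, ("a", "b"): 0.7})
res = reconstruct_pathways(net, PathQuery(sources=["s"], targets=["t"], k=5),
                           CostConfig("probability"))
print([(p.rank, p.score, p.nodes) for p in res.paths])
# [(1, 0.81, ('s', 'b', 't')), (2, 0.315, ('s', 'a', 'b', 't')), (3, 0.25, ('s', 'a', 't'))]
```

Two further subcommands: `pathrank strongest` runs the through-node
shortest-path baseline (one best path per node within a slack τ of the
optimum — provably incomplete, see `docs/methods.md`), and
`pathrank generate` writes reproducible synthetic networks.

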