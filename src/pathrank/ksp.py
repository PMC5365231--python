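"""k shortest loopless paths: Dijkstra, A*, and Yen's algorithm.

This is the algorithmic core of the package and is written from first
principles (the surrounding ecosystem's k-shortest-path routines serve only
as independent cross-checks in the test suite).

Design points that matter for reproducibility:

* Every search uses one global total order on paths:
  ``(internal cost, number of edges, lexicographic node sequence)``.
  Node identifiers are mapped to integer indices in sorted-identifier order,
  so integer tuple comparison equals lexicographic identifier comparison.
  Heap entries carry the full path tuple, which makes tie-breaking exact and
  platform-independent; the order is extension-monotone (appending an edge
  never decreases it), so settle-on-first-pop Dijkstra/A* returns the unique
  minimum under it.
* Costs are compared exactly as floats, no epsilon.
* Yen's temporary removals use hidden-edge / hidden-node sets on the costed
  graph rather than topology mutation; hiding is O(1) and fully reversible,
  and the engine restores empty hidden sets before returning.
* The A* heuristic is the reverse-traversal Dijkstra distance-to-anchor
  computed once on the full (unhidden) graph.  Hiding elements only removes
  options, so those distances stay admissible — and consistent — lower
  bounds for every spur search.
"""

from __future__ import annotations

import heapq
import math
from collections import defaultdict
from dataclasses import dataclass
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence, Tuple

INF = math.inf

__all__ = [
    "CostedGraph",
    "DistanceMap",
    "RankedPath",
    "KspValidationError",
    "reverse_dijkstra",
    "astar_shortest_path",
    "yen_ksp",
]


class KspValidationError(ValueError):
    pass


@dataclass
class RankedPath:
    """One ranked loopless path.

    ``internal_cost`` is the summed (possibly penalised) additive cost the
    engine minimised; ``score`` is the user-facing score filled in by the
    reconstruction layer (edge count / weight sum / weight product).
    """

    rank: Optional[int]
    nodes: Tuple[str, ...]
    internal_cost: float
    score: Optional[float] = None


class CostedGraph:
    """Directed graph with non-negative finite edge costs and hidden sets.

    Nodes are registered under their string identifiers but stored as
    integer indices assigned in sorted-identifier order (see module notes).
    ``hide_edge`` / ``hide_node`` make elements invisible to every traversal
    without touching the topology; ``restore_all`` reverses all hiding.
    """

    __slots__ = ("names", "_index", "_adj", "_radj", "_hidden_nodes", "_hidden_edges")

    def __init__(self, nodes: Iterable[str], edges: Iterable[Tuple[str, str, float]]):
        names = sorted(set(nodes))
        self.names: List[str] = names
        self._index: Dict[str, int] = {n: i for i, n in enumerate(names)}
        n = len(names)
        self._adj: List[Dict[int, float]] = [dict() for _ in range(n)]
        self._radj: List[Dict[int, float]] = [dict() for _ in range(n)]
        for u, v, c in edges:
            if not (c >= 0.0) or not math.isfinite(c):
                raise KspValidationError(f"edge ({u!r}, {v!r}) has invalid cost {c!r}")
            ui, vi = self._index[u], self._index[v]
            self._adj[ui][vi] = c
            self._radj[vi][ui] = c
        self._hidden_nodes: set[int] = set()
        self._hidden_edges: set[Tuple[int, int]] = set()

    @classmethod
    def from_network(cls, network, config) -> "CostedGraph":
        """Build the costed graph of a :class:`~pathrank.network.Network`
        under a :class:`~pathrank.costs.CostConfig`."""
        from .costs import edge_cost, validate_network_weights

        validate_network_weights(network, config)
        return cls(
            network.nodes,
            ((u, v, edge_cost(w, config)) for (u, v), w in network.edges.items()),
        )

    # -- introspection ------------------------------------------------------

    def __contains__(self, node: str) -> bool:
        return node in self._index

    @property
    def n_nodes(self) -> int:
        return len(self.names)

    def cost(self, tail: str, head: str) -> float:
        return self._adj[self._index[tail]][self._index[head]]

    def out_edges(self, tail: str) -> Iterator[Tuple[str, float]]:
        """Visible out-edges of ``tail`` (hidden elements skipped)."""
        ui = self._index[tail]
        if ui in self._hidden_nodes:
            return
        for vi, c in self._adj[ui].items():
            if vi not in self._hidden_nodes and (ui, vi) not in self._hidden_edges:
                yield self.names[vi], c

    # -- hiding -------------------------------------------------------------

    def hide_edge(self, tail: str, head: str) -> None:
        self._hidden_edges.add((self._index[tail], self._index[head]))

    def hide_node(self, node: str) -> None:
        self._hidden_nodes.add(self._index[node])

    def restore_all(self) -> None:
        self._hidden_nodes.clear()
        self._hidden_edges.clear()

    @property
    def hidden_empty(self) -> bool:
        return not self._hidden_nodes and not self._hidden_edges


class DistanceMap(Mapping):
    """Per-node shortest-path cost to a fixed anchor (+inf if unreachable)."""

    def __init__(self, graph: CostedGraph, values: List[float], anchor: str):
        self._graph = graph
        self._values = values
        self.anchor = anchor

    def __getitem__(self, node: str) -> float:
        return self._values[self._graph._index[node]]

    def __iter__(self):
        return iter(self._graph.names)

    def __len__(self):
        return len(self._values)


def reverse_dijkstra(graph: CostedGraph, anchor: str) -> DistanceMap:
    """Cheapest directed v→anchor cost for every node v.

    Traverses in-edges from the anchor outward — the graph is never
    reversed.  Runs on the full topology (hidden sets are ignored), which is
    what makes the result an admissible A* heuristic for any subsequently
    hidden configuration.
    """
    ai = graph._index[anchor]  # KeyError if absent, per contract
    radj = graph._radj
    n = graph.n_nodes
    dist = [INF] * n
    dist[ai] = 0.0
    done = [False] * n
    heap: List[Tuple[float, int]] = [(0.0, ai)]
    while heap:
        d, v = heapq.heappop(heap)
        if done[v]:
            continue
        done[v] = True
        for u, c in radj[v].items():
            nd = d + c
            if nd < dist[u]:
                dist[u] = nd
                heapq.heappush(heap, (nd, u))
    return DistanceMap(graph, dist, anchor)


def _search(
    graph: CostedGraph, origin: int, anchor: int, h: Optional[List[float]]
) -> Optional[Tuple[float, Tuple[int, ...]]]:
    """Single-pair A* (Dijkstra when ``h`` is None) respecting hidden sets.

    Returns ``(cost, path-as-index-tuple)`` minimal under the global order,
    or None when disconnected.  Heap entries are ``(f, edges, path, g)``.
    """
    hidden_nodes = graph._hidden_nodes
    hidden_edges = graph._hidden_edges
    adj = graph._adj
    if origin in hidden_nodes or anchor in hidden_nodes:
        return None
    h0 = h[origin] if h is not None else 0.0
    if h0 == INF:
        return None
    if origin == anchor:
        return 0.0, (origin,)
    settled: set[int] = set()
    best_g: Dict[int, float] = {origin: 0.0}
    heap: List[Tuple[float, int, Tuple[int, ...], float]] = [(h0, 0, (origin,), 0.0)]
    pop = heapq.heappop
    push = heapq.heappush
    while heap:
        f, e, path, g = pop(heap)
        u = path[-1]
        if u in settled:
            continue
        settled.add(u)
        if u == anchor:
            return g, path
        e1 = e + 1
        for v, c in adj[u].items():
            if v in settled or v in hidden_nodes or (u, v) in hidden_edges:
                continue
            hv = h[v] if h is not None else 0.0
            if hv == INF:
                continue
            ng = g + c
            bg = best_g.get(v)
            if bg is not None and ng > bg:
                continue
            if bg is None or ng < bg:
                best_g[v] = ng
            push(heap, (ng + hv, e1, path + (v,), ng))
    return None


def astar_shortest_path(
    graph: CostedGraph,
    origin: str,
    anchor: str,
    heuristic: Optional[DistanceMap] = None,
) -> Optional[RankedPath]:
    """Minimum-internal-cost origin→anchor path respecting hidden sets.

    With an admissible ``heuristic`` (reverse-Dijkstra distances on the
    unhidden graph) the result is identical to plain Dijkstra's, including
    tie-breaking.  Returns None when the endpoints are disconnected.
    """
    oi = graph._index[origin]
    ai = graph._index[anchor]
    h = heuristic._values if heuristic is not None else None
    found = _search(graph, oi, ai, h)
    if found is None:
        return None
    cost, path = found
    return RankedPath(rank=None, nodes=tuple(graph.names[i] for i in path), internal_cost=cost)


def yen_ksp(
    graph: CostedGraph,
    origin: str,
    anchor: str,
    k: int,
    heuristic: Optional[DistanceMap] = None,
) -> List[RankedPath]:
    """Yen's k shortest loopless paths, accelerated with A*.

    Spur candidates for the i-th accepted path hide (a) every node of the
    root prefix except the spur node — which is what makes the output
    loopless by construction — and (b) the next edge of every previously
    accepted path sharing that root prefix.  Candidates are de-duplicated by
    node sequence and drawn from a pool ordered by the global path order, so
    the output is deterministic and sorted non-decreasing in cost.  The gap
    guarantee follows: no loopless origin→anchor path has cost strictly
    between two consecutive returned costs.

    Hidden sets must be empty on entry and are empty again on return.
    """
    if not isinstance(k, int) or isinstance(k, bool) or k < 1:
        raise KspValidationError(f"k must be a positive integer, got {k!r}")
    if not graph.hidden_empty:
        raise KspValidationError("yen_ksp requires empty hidden sets on entry")
    oi = graph._index[origin]
    ai = graph._index[anchor]
    h = heuristic._values if heuristic is not None else None
    adj = graph._adj
    hidden_nodes = graph._hidden_nodes
    hidden_edges = graph._hidden_edges

    try:
        first = _search(graph, oi, ai, h)
        if first is None:
            return []
        accepted: List[Tuple[float, Tuple[int, ...]]] = [first]  # (cost, path)
        seen: set[Tuple[int, ...]] = {first[1]}
        # prefix -> set of next-hop indices over accepted paths, for O(1)
        # lookup of the edges Yen must hide at each spur position
        prefix_next: Dict[Tuple[int, ...], set[int]] = defaultdict(set)

        def register(path: Tuple[int, ...]) -> None:
            for j in range(len(path) - 1):
                prefix_next[path[: j + 1]].add(path[j + 1])

        register(first[1])
        pool: List[Tuple[float, int, Tuple[int, ...]]] = []

        while len(accepted) < k:
            prev_path = accepted[-1][1]
            for j in range(len(prev_path) - 1):
                root = prev_path[: j + 1]
                spur = prev_path[j]
                for nxt in prefix_next.get(root, ()):
                    hidden_edges.add((spur, nxt))
                hidden_nodes.update(root[:-1])
                spur_found = _search(graph, spur, ai, h)
                hidden_nodes.clear()
                hidden_edges.clear()
                if spur_found is None:
                    continue
                total = root[:-1] + spur_found[1]
                if total in seen:
                    continue
                seen.add(total)
                # accumulate strictly left to right so the float value is
                # identical no matter where the path was spurred
                cost = 0.0
                for a, b in zip(total, total[1:]):
                    cost += adj[a][b]
                heapq.heappush(pool, (cost, len(total) - 1, total))
            if not pool:
                break
            cost, _, path = heapq.heappop(pool)
            accepted.append((cost, path))
            register(path)
    finally:
        graph.restore_all()

    names = graph.names
    return [
        RankedPath(rank=i + 1, nodes=tuple(names[x] for x in p), internal_cost=c)
        for i, (c, p) in enumerate(accepted)
    ]


def _label_dijkstra(
    graph: CostedGraph, start: str, reverse: bool = False
) -> Dict[str, Tuple[float, Tuple[str, ...]]]:
    """Deterministic single-source search returning, for every reachable
    node, its cost and the minimal path under the global order.

    With ``reverse`` the traversal follows in-edges and the recorded path
    runs from ``start`` backwards (callers reverse it).  Stores one full
    path per node — meant for modest graphs (the through-node baseline),
    not the hot path.
    """
    si = graph._index[start]
    adj = graph._radj if reverse else graph._adj
    hidden_nodes = graph._hidden_nodes
    hidden_edges = graph._hidden_edges
    out: Dict[int, Tuple[float, Tuple[int, ...]]] = {}
    heap: List[Tuple[float, int, Tuple[int, ...]]] = [(0.0, 0, (si,))]
    while heap:
        g, e, path = heapq.heappop(heap)
        u = path[-1]
        if u in out:
            continue
        out[u] = (g, path)
        for v, c in adj[u].items():
            if v in out or v in hidden_nodes:
                continue
            pair = (v, u) if reverse else (u, v)
            if pair in hidden_edges:
                continue
            heapq.heappush(heap, (g + c, e + 1, path + (v,)))
    names = graph.names
    return {
        names[i]: (g, tuple(names[x] for x in p)) for i, (g, p) in out.items()
    }
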