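"""Through-node shortest-path baseline.

A simpler family of tools answers the source→target connection question by
computing, for every node v, the shortest path that starts at some source,
passes through v, and ends at some target, then emitting the paths of the
nodes whose through-cost d(v) is within a slack τ of the optimum.  The
procedure: attach a super source s* and super target t*, run a forward
Dijkstra from s* and a reverse-traversal Dijkstra from t*, set
d(v) = dist(s*, v) + dist(v, t*), let a = min_v d(v), and output π_v for
every v with d(v) ≤ a + τ in increasing d(v).

Because at most one path is kept per node, at most n distinct paths can
ever be produced — the procedure cannot enumerate all near-optimal paths
the way the k-shortest-paths engine can, and the test suite demonstrates a
network where a within-slack path is missed for exactly that reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import List, Sequence, Tuple

from .costs import CostConfig, edge_cost, validate_network_weights
from .ksp import CostedGraph, _label_dijkstra
from .network import Network
from .reconstruct import _fresh_name, validate_endpoints

logger = logging.getLogger(__name__)

__all__ = ["ThroughNodePath", "strongest_paths"]


@dataclass
class ThroughNodePath:
    """Best source→target path through ``via``; ``d_value`` is its cost."""

    via: str
    d_value: float
    path: Tuple[str, ...]


def strongest_paths(
    network: Network,
    sources: Sequence[str],
    targets: Sequence[str],
    tau: float,
    config: CostConfig,
    *,
    strict_endpoints: bool = False,
) -> List[ThroughNodePath]:
    """Emit the through-node path π_v for every node v with d(v) ≤ a + τ.

    Results are sorted by (d(v), node identifier).  If concatenating the
    forward and backward half-paths at v repeats a node, that node's path
    is discarded with a warning (the junction formed a loop).
    """
    if tau < 0:
        raise ValueError(f"tau must be non-negative, got {tau!r}")
    kept_sources, kept_targets, _ = validate_endpoints(
        network, sources, targets, strict=strict_endpoints
    )
    validate_network_weights(network, config)

    edges = [(u, v, edge_cost(w, config)) for (u, v), w in network.edges.items()]
    s_star = _fresh_name("<SOURCE>", network.nodes)
    t_star = _fresh_name("<TARGET>", network.nodes | {s_star})
    for s in kept_sources:
        edges.append((s_star, s, 0.0))
    for t in kept_targets:
        edges.append((t, t_star, 0.0))
    graph = CostedGraph(set(network.nodes) | {s_star, t_star}, edges)

    forward = _label_dijkstra(graph, s_star)               # s* -> v
    backward = _label_dijkstra(graph, t_star, reverse=True)  # recorded t* -> v

    candidates: List[ThroughNodePath] = []
    best = None
    for v in sorted(network.nodes):
        if v not in forward or v not in backward:
            continue
        g_fwd, p_fwd = forward[v]
        g_bwd, p_bwd = backward[v]
        d = g_fwd + g_bwd
        if best is None or d < best:
            best = d
        full = p_fwd + tuple(reversed(p_bwd))[1:]  # s*..v + v..t* minus duplicate v
        path = full[1:-1]  # strip super endpoints
        if len(set(path)) != len(path):
            logger.warning("through-node path for %r repeats a node; discarded", v)
            continue
        candidates.append(ThroughNodePath(via=v, d_value=d, path=path))

    if best is None:
        return []
    emitted = [c for c in candidates if c.d_value <= best + tau]
    emitted.sort(key=lambda c: (c.d_value, c.via))
    return emitted
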