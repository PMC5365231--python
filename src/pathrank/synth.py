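"""Synthetic networks and the brute-force loopless-path oracle.

The generator draws Erdős–Rényi-style directed graphs (either a per-pair
edge probability or an exact edge count) with weights matched to a weight
mode: reliabilities uniform in (0, 1] for probability mode, uniform in
(0, 10] for additive mode, absent for unweighted.  Weights are rounded to
six decimals so written fixtures are platform-stable; a rounded weight of
exactly zero is bumped to 1e-6 to stay inside the probability domain.  The
same spec and seed always produce the identical network.

The oracle enumerates *all* loopless origin→anchor paths by depth-first
search — exponential, hence guarded to small graphs — applying the exact
same cost transform and (cost, edge count, lexicographic nodes) tie order
as the search engine, so comparisons against it are exact, not approximate.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .costs import CostConfig, WeightMode
from .ksp import CostedGraph
from .network import Network

ORACLE_MAX_NODES = 12

__all__ = [
    "GeneratorSpec",
    "OracleGuardError",
    "generate_network",
    "enumerate_all_paths",
    "enumerate_costed_paths",
]


class OracleGuardError(ValueError):
    """The graph is too large for exhaustive path enumeration."""


@dataclass(frozen=True)
class GeneratorSpec:
    """Reproducible random-network recipe.

    Exactly one of ``edge_probability`` (per ordered pair) or ``m_edges``
    (exact count, sampled without replacement) must be given.
    ``weight_bounds`` defaults to the mode's conventional range.
    """

    n_nodes: int
    edge_probability: Optional[float] = None
    m_edges: Optional[int] = None
    weight_mode: WeightMode = WeightMode.UNWEIGHTED
    weight_bounds: Optional[Tuple[float, float]] = None
    seed: int = 0

    def __post_init__(self):
        object.__setattr__(self, "weight_mode", WeightMode(self.weight_mode))
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be >= 2")
        if (self.edge_probability is None) == (self.m_edges is None):
            raise ValueError("give exactly one of edge_probability or m_edges")
        if self.edge_probability is not None and not (0.0 <= self.edge_probability <= 1.0):
            raise ValueError(f"edge_probability must be in [0, 1], got {self.edge_probability!r}")
        max_edges = self.n_nodes * (self.n_nodes - 1)
        if self.m_edges is not None and not (0 <= self.m_edges <= max_edges):
            raise ValueError(
                f"m_edges must be in [0, {max_edges}] for {self.n_nodes} nodes, "
                f"got {self.m_edges!r}"
            )

    @property
    def bounds(self) -> Optional[Tuple[float, float]]:
        if self.weight_mode is WeightMode.UNWEIGHTED:
            return None
        if self.weight_bounds is not None:
            return self.weight_bounds
        return (0.0, 1.0) if self.weight_mode is WeightMode.PROBABILITY else (0.0, 10.0)


def generate_network(spec: GeneratorSpec) -> Network:
    """Sample the network described by ``spec`` (deterministic in the seed)."""
    rng = np.random.default_rng(spec.seed)
    width = len(str(spec.n_nodes - 1))
    names = [f"n{i:0{width}d}" for i in range(spec.n_nodes)]
    pairs = [(u, v) for u in names for v in names if u != v]

    if spec.edge_probability is not None:
        mask = rng.random(len(pairs)) < spec.edge_probability
        chosen = [p for p, m in zip(pairs, mask) if m]
    else:
        idx = sorted(rng.choice(len(pairs), size=spec.m_edges, replace=False).tolist())
        chosen = [pairs[i] for i in idx]

    edges: dict = {}
    if spec.bounds is None:
        for pair in chosen:
            edges[pair] = None
    else:
        low, high = spec.bounds
        draws = high - rng.random(len(chosen)) * (high - low)  # uniform in (low, high]
        weights = np.maximum(np.round(draws, 6), 1e-6)
        for pair, w in zip(chosen, weights):
            edges[pair] = float(w)
    return Network(nodes=set(names), edges=edges)


def enumerate_costed_paths(
    graph: CostedGraph, origin: str, anchor: str, max_nodes: int = ORACLE_MAX_NODES
) -> List[Tuple[Tuple[str, ...], float]]:
    """All loopless origin→anchor paths of a costed graph, sorted by the
    global (cost, edges, lexicographic) order.  Hidden elements are
    respected.  ``origin == anchor`` yields no paths (pipeline semantics:
    a loopless path cannot revisit its own start)."""
    if graph.n_nodes > max_nodes:
        raise OracleGuardError(
            f"{graph.n_nodes} nodes exceeds the enumeration guard ({max_nodes})"
        )
    if origin not in graph or anchor not in graph:
        raise KeyError(f"origin or anchor not in graph: {origin!r}, {anchor!r}")
    if origin == anchor:
        return []

    found: List[Tuple[float, int, Tuple[str, ...]]] = []
    path: List[str] = [origin]
    visited = {origin}

    def walk(node: str, cost: float) -> None:
        for nxt, c in graph.out_edges(node):
            if nxt in visited:
                continue
            path.append(nxt)
            if nxt == anchor:
                found.append((cost + c, len(path) - 1, tuple(path)))
            else:
                visited.add(nxt)
                walk(nxt, cost + c)
                visited.discard(nxt)
            path.pop()

    walk(origin, 0.0)
    found.sort()
    return [(p, c) for c, _, p in found]


def enumerate_all_paths(
    network: Network,
    origin: str,
    anchor: str,
    config: CostConfig,
    max_nodes: int = ORACLE_MAX_NODES,
) -> List[Tuple[Tuple[str, ...], float]]:
    """Ground truth for the k-shortest-paths engine on a plain network."""
    graph = CostedGraph.from_network(network, config)
    return enumerate_costed_paths(graph, origin, anchor, max_nodes=max_nodes)
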