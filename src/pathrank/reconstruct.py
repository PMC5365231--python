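"""Source→target pathway reconstruction pipeline.

Given a weighted directed interaction network, a set of source nodes
(e.g. receptors) and a set of target nodes (e.g. transcription factors),
compute the k best-scoring loopless source-to-target paths and assemble the
annotated sub-network they induce.  Set-to-set search reduces to single-pair
search through an auxiliary super source s* (zero-cost edges to every
source) and super target t* (zero-cost edges from every target); super
elements never contribute to costs or scores and are stripped from every
reported path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

from .costs import CostConfig, path_score, validate_network_weights, edge_cost
from .ksp import CostedGraph, RankedPath, reverse_dijkstra, yen_ksp
from .network import Network, ordered_unique

logger = logging.getLogger(__name__)

DEFAULT_K = 200

__all__ = [
    "DEFAULT_K",
    "EndpointError",
    "PathQuery",
    "Subnetwork",
    "ReconstructionResult",
    "validate_endpoints",
    "prepare_query_graph",
    "reconstruct_pathways",
    "compute_subnetwork",
]


class EndpointError(ValueError):
    """No usable source or no usable target remains — the run must stop."""


def _coerce_k(k) -> int:
    """Invalid k (non-integer, non-positive) falls back to the default with
    a warning, mirroring the interactive app's behaviour."""
    if isinstance(k, bool) or not isinstance(k, int):
        if isinstance(k, float) and k.is_integer() and k >= 1:
            return int(k)
        logger.warning("invalid k %r; using default %d", k, DEFAULT_K)
        return DEFAULT_K
    if k < 1:
        logger.warning("invalid k %r; using default %d", k, DEFAULT_K)
        return DEFAULT_K
    return k


@dataclass
class PathQuery:
    """What to reconstruct: endpoints, k, and endpoint-handling options.

    ``targets_are_sources`` copies the sources into the targets and forces
    ``allow_sources_targets_in_paths`` (connecting a set to itself only
    makes sense if its members may sit inside paths).
    """

    sources: Sequence[str]
    targets: Sequence[str] = ()
    k: int = DEFAULT_K
    allow_sources_targets_in_paths: bool = False
    targets_are_sources: bool = False

    def __post_init__(self):
        self.sources = ordered_unique(str(s).strip() for s in self.sources)
        if self.targets_are_sources:
            self.targets = list(self.sources)
            self.allow_sources_targets_in_paths = True
        else:
            self.targets = ordered_unique(str(t).strip() for t in self.targets)
        self.k = _coerce_k(self.k)


@dataclass
class Subnetwork:
    """Union of the nodes and edges of the returned paths, each annotated
    with the rank of the first path containing it."""

    node_index: dict = field(default_factory=dict)          # node -> first-path rank
    edge_index: dict = field(default_factory=dict)          # (tail, head) -> first-path rank
    edge_weight: dict = field(default_factory=dict)         # (tail, head) -> original weight

    @property
    def n_nodes(self) -> int:
        return len(self.node_index)

    @property
    def n_edges(self) -> int:
        return len(self.edge_index)


@dataclass
class ReconstructionResult:
    paths: List[RankedPath]
    subnetwork: Subnetwork
    warnings: List[str] = field(default_factory=list)

    def __iter__(self):
        yield self.paths
        yield self.subnetwork


def validate_endpoints(
    network: Network,
    sources: Sequence[str],
    targets: Sequence[str],
    strict: bool = False,
) -> Tuple[List[str], List[str], List[str]]:
    """Drop endpoints absent from the network, one warning per absence.

    Raises :class:`EndpointError` when no source or no target survives, or
    when ``strict`` and any endpoint is absent (the non-interactive stand-in
    for refusing the app's continue-anyway dialog).
    """
    warnings: List[str] = []

    def check(kind: str, given: Sequence[str]) -> List[str]:
        kept = [n for n in given if n in network.nodes]
        for missing in (n for n in given if n not in network.nodes):
            msg = f"{kind} {missing!r} is not a node of the network"
            warnings.append(msg)
            logger.warning("%s", msg)
        return kept

    kept_sources = check("source", ordered_unique(sources))
    kept_targets = check("target", ordered_unique(targets))
    if strict and warnings:
        raise EndpointError("; ".join(warnings))
    if not kept_sources:
        raise EndpointError("none of the sources are in the network")
    if not kept_targets:
        raise EndpointError("none of the targets are in the network")
    return kept_sources, kept_targets, warnings


def _fresh_name(base: str, taken) -> str:
    name = base
    while name in taken:
        name += "_"
    return name


def prepare_query_graph(
    network: Network, query: PathQuery, config: CostConfig
) -> Tuple[CostedGraph, str, str]:
    """Build the costed query graph: cost-transformed edges, endpoint-edge
    removal, and super source/target attachment.

    Unless ``allow_sources_targets_in_paths``, edges into any source and out
    of any target are removed so endpoints can only open or close a path.
    Super edges carry cost exactly 0 in every mode, so neither costs nor
    scores ever count them.  Returns the graph plus the generated super
    source and super target identifiers.
    """
    validate_network_weights(network, config)
    sources = set(query.sources)
    targets = set(query.targets)
    edges: List[Tuple[str, str, float]] = []
    for (u, v), w in network.edges.items():
        if not query.allow_sources_targets_in_paths and (v in sources or u in targets):
            continue
        edges.append((u, v, edge_cost(w, config)))
    s_star = _fresh_name("<SOURCE>", network.nodes)
    t_star = _fresh_name("<TARGET>", network.nodes | {s_star})
    nodes = set(network.nodes) | {s_star, t_star}
    for s in query.sources:
        edges.append((s_star, s, 0.0))
    for t in query.targets:
        edges.append((t, t_star, 0.0))
    return CostedGraph(nodes, edges), s_star, t_star


def compute_subnetwork(paths: Sequence[RankedPath], network: Network) -> Subnetwork:
    """Union of path nodes/edges annotated with first-path indices; weights
    copied from the network."""
    sub = Subnetwork()
    for p in paths:
        for node in p.nodes:
            sub.node_index.setdefault(node, p.rank)
        for u, v in zip(p.nodes, p.nodes[1:]):
            if (u, v) not in network.edges:
                raise KeyError(f"path {p.rank} uses edge ({u!r}, {v!r}) absent from the network")
            sub.edge_index.setdefault((u, v), p.rank)
            sub.edge_weight[(u, v)] = network.edges[(u, v)]
    return sub


def reconstruct_pathways(
    network: Network,
    query: PathQuery,
    config: Optional[CostConfig] = None,
    *,
    strict_endpoints: bool = False,
) -> ReconstructionResult:
    """Run the full reconstruction pipeline.

    Validates endpoints, prepares the query graph, computes the A*
    heuristic (reverse-traversal Dijkstra distances to the super target),
    runs Yen's algorithm, strips super elements, attaches user-facing
    scores, ranks paths 1..n, and assembles the annotated sub-network.

    A node that is both a source and a target would admit the degenerate
    hop s*→v→t*, which contains no real edge; those are filtered out (a
    single self-connected node therefore yields no paths at all) and the
    engine is asked for correspondingly more paths so k real paths can
    still be returned.
    """
    if config is None:
        config = CostConfig()
    if not network.nodes:
        raise EndpointError("the network is empty")
    kept_sources, kept_targets, warnings = validate_endpoints(
        network, query.sources, query.targets, strict=strict_endpoints
    )
    query = replace(query, sources=kept_sources, targets=kept_targets)
    graph, s_star, t_star = prepare_query_graph(network, query, config)
    heuristic = reverse_dijkstra(graph, t_star)
    overlap = len(set(query.sources) & set(query.targets))
    raw = yen_ksp(graph, s_star, t_star, query.k + overlap, heuristic)

    paths: List[RankedPath] = []
    for rp in raw:
        inner = rp.nodes[1:-1]  # strip s* and t*
        if len(inner) < 2:
            continue  # degenerate s*→v→t* hop, no real edge
        paths.append(
            RankedPath(
                rank=len(paths) + 1,
                nodes=inner,
                internal_cost=rp.internal_cost,
                score=path_score(inner, network, config),
            )
        )
        if len(paths) == query.k:
            break
    subnetwork = compute_subnetwork(paths, network)
    return ReconstructionResult(paths=paths, subnetwork=subnetwork, warnings=warnings)
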