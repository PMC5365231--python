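"""Directed interaction networks and the plain-text edge-list formats around them.

The in-memory container is deliberately small: a node set plus a mapping
``(tail, head) -> weight``.  Node identifiers are opaque, case-sensitive,
whitespace-trimmed strings (UniProt accessions, gene symbols, ...).  A network
is either fully weighted or fully unweighted; mixing the two is rejected at
load time because the downstream cost transform cannot interpret it.
"""

from __future__ import annotations

import logging
import math
import os
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Optional, Sequence, Union

logger = logging.getLogger(__name__)

__all__ = [
    "Network",
    "NetworkParseError",
    "NetworkValidationError",
    "ordered_unique",
    "read_edge_list",
    "write_edge_list",
    "write_path_table",
    "write_subnetwork",
]


class NetworkParseError(ValueError):
    """A line of an edge-list file could not be parsed."""

    def __init__(self, message: str, line_number: Optional[int] = None):
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)
        self.line_number = line_number


class NetworkValidationError(ValueError):
    """An edge list parsed cleanly but violates a network invariant."""


def ordered_unique(items: Iterable[str]) -> list[str]:
    """De-duplicate while preserving first-occurrence order (node lists)."""
    seen: set[str] = set()
    out: list[str] = []
    for item in items:
        if item not in seen:
            seen.add(item)
            out.append(item)
    return out


@dataclass
class Network:
    """A directed graph with optional non-negative real edge weights.

    Invariants (enforced by :func:`read_edge_list` and checked by
    :meth:`validate`): no self-loops, no duplicate ``(tail, head)`` keys,
    every edge endpoint is in ``nodes``, and either every edge carries a
    weight or none does.
    """

    nodes: set[str] = field(default_factory=set)
    edges: dict[tuple[str, str], Optional[float]] = field(default_factory=dict)

    @property
    def weighted(self) -> bool:
        return any(w is not None for w in self.edges.values())

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def weight(self, tail: str, head: str) -> Optional[float]:
        return self.edges[(tail, head)]

    def __contains__(self, node: str) -> bool:
        return node in self.nodes

    def validate(self) -> None:
        flags = {w is not None for w in self.edges.values()}
        if len(flags) > 1:
            raise NetworkValidationError("mixed weighted and unweighted edges")
        for (u, v), w in self.edges.items():
            if u == v:
                raise NetworkValidationError(f"self-loop on {u!r}")
            if u not in self.nodes or v not in self.nodes:
                raise NetworkValidationError(f"edge ({u!r}, {v!r}) endpoint not in node set")
            if w is not None and (not math.isfinite(w) or w < 0):
                raise NetworkValidationError(f"edge ({u!r}, {v!r}) has invalid weight {w!r}")


Source = Union[str, os.PathLike, IO[str]]


def _open_maybe(source: Source, mode: str = "r"):
    if isinstance(source, (str, os.PathLike)):
        return open(source, mode, encoding="utf-8", newline=""), True
    return source, False


def read_edge_list(
    source: Source,
    dialect: str = "tsv",
    treat_undirected_as_bidirected: bool = False,
) -> Network:
    """Read a directed network from a TSV edge list or a SIF file.

    TSV lines are ``tail<TAB>head[<TAB>weight]``; SIF lines are
    ``tail relation head`` (whitespace-separated, always unweighted, the
    relation column is discarded).  Lines starting with ``#`` and blank
    lines are skipped.  Self-loops are dropped with a warning; duplicate
    ``(tail, head)`` edges keep the maximum weight (strongest evidence)
    with a logged collision.  With ``treat_undirected_as_bidirected`` each
    input edge also yields its reverse with the same weight.

    Raises :class:`NetworkParseError` for malformed lines (naming the line
    number) and :class:`NetworkValidationError` for negative weights or a
    mix of weighted and unweighted lines.
    """
    dialect = dialect.lower()
    if dialect not in ("tsv", "sif"):
        raise ValueError(f"unknown dialect {dialect!r}; expected 'tsv' or 'sif'")

    handle, close = _open_maybe(source)
    nodes: set[str] = set()
    edges: dict[tuple[str, str], Optional[float]] = {}
    weighted_seen: Optional[bool] = None
    try:
        for lineno, raw in enumerate(handle, start=1):
            line = raw.rstrip("\r\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            weight: Optional[float] = None
            if dialect == "tsv":
                cols = line.split("\t")
                if len(cols) not in (2, 3):
                    raise NetworkParseError(
                        f"expected 2 or 3 tab-separated columns, found {len(cols)}", lineno
                    )
                tail, head = cols[0].strip(), cols[1].strip()
                if len(cols) == 3:
                    text = cols[2].strip()
                    try:
                        weight = float(text)
                    except ValueError:
                        raise NetworkParseError(f"unparseable weight {text!r}", lineno) from None
                    if not math.isfinite(weight):
                        raise NetworkValidationError(f"line {lineno}: non-finite weight {text!r}")
                    if weight < 0:
                        raise NetworkValidationError(f"line {lineno}: negative weight {weight!r}")
            else:
                cols = line.split()
                if len(cols) != 3:
                    raise NetworkParseError(
                        f"expected 3 whitespace-separated SIF columns, found {len(cols)}", lineno
                    )
                tail, head = cols[0], cols[2]
            if not tail or not head:
                raise NetworkParseError("empty node identifier", lineno)

            has_weight = weight is not None
            if weighted_seen is None:
                weighted_seen = has_weight
            elif weighted_seen != has_weight:
                raise NetworkValidationError(
                    f"line {lineno}: mixed weighted and unweighted edges"
                )

            pairs = [(tail, head)]
            if treat_undirected_as_bidirected:
                pairs.append((head, tail))
            for u, v in pairs:
                nodes.add(u)
                nodes.add(v)
                if u == v:
                    logger.warning("dropping self-loop on %r (line %d)", u, lineno)
                    continue
                if (u, v) in edges:
                    old = edges[(u, v)]
                    kept = old if weight is None else max(old, weight)  # type: ignore[arg-type]
                    logger.warning(
                        "duplicate edge (%r, %r) at line %d: keeping weight %s", u, v, lineno, kept
                    )
                    edges[(u, v)] = kept
                else:
                    edges[(u, v)] = weight
    finally:
        if close:
            handle.close()
    return Network(nodes=nodes, edges=edges)


def _fmt_number(value) -> str:
    if value is None:
        return ""
    if isinstance(value, int):
        return str(value)
    if isinstance(value, float) and value.is_integer():
        return str(int(value))
    return repr(float(value))


def write_edge_list(network: Network, dest: Source) -> None:
    """Write a network as a TSV edge list (tail, head[, weight]), sorted."""
    handle, close = _open_maybe(dest, "w")
    try:
        for (u, v) in sorted(network.edges):
            w = network.edges[(u, v)]
            if w is None:
                handle.write(f"{u}\t{v}\n")
            else:
                handle.write(f"{u}\t{v}\t{_fmt_number(w)}\n")
    finally:
        if close:
            handle.close()


def write_path_table(paths: Sequence, dest: Source) -> None:
    """Write ranked paths as TSV: rank, score, pipe-delimited node sequence."""
    handle, close = _open_maybe(dest, "w")
    try:
        handle.write("rank\tscore\tpath\n")
        for p in paths:
            handle.write(f"{p.rank}\t{_fmt_number(p.score)}\t{'|'.join(p.nodes)}\n")
    finally:
        if close:
            handle.close()


def write_subnetwork(sub, edges_dest: Source, nodes_dest: Source) -> None:
    """Write a sub-network as an edge table and a node table.

    Edge table columns: tail, head, weight (empty if unweighted),
    edge_first_path_index.  Node table columns: node,
    node_first_path_index.  Rows are sorted by (first-path index, id).
    """
    handle, close = _open_maybe(edges_dest, "w")
    try:
        handle.write("tail\thead\tweight\tedge_first_path_index\n")
        for (u, v) in sorted(sub.edge_index, key=lambda e: (sub.edge_index[e], e)):
            w = _fmt_number(sub.edge_weight[(u, v)])
            handle.write(f"{u}\t{v}\t{w}\t{sub.edge_index[(u, v)]}\n")
    finally:
        if close:
            handle.close()
    handle, close = _open_maybe(nodes_dest, "w")
    try:
        handle.write("node\tnode_first_path_index\n")
        for node in sorted(sub.node_index, key=lambda n: (sub.node_index[n], n)):
            handle.write(f"{node}\t{sub.node_index[node]}\n")
    finally:
        if close:
            handle.close()
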