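"""Edge-weight interpretation: user-facing scores vs. internal additive costs.

All shortest-path machinery runs on a non-negative additive cost per edge.
Three weight modes map user weights onto that cost:

* ``unweighted``  — every edge costs 1; a path's score is its edge count
  (lower is better).
* ``additive``    — cost = weight + edge_penalty; a path's score is the sum
  of its raw weights (lower is better).
* ``probability`` — weights in (0, 1] are experimental reliabilities; cost =
  |log(weight)| + log(edge_penalty), so minimising summed cost maximises the
  product of weights.  A path's score is that product (higher is better).

The edge penalty is a per-edge surcharge discouraging long paths: additive in
cost space, hence multiplicative (log-transformed) for probability weights.
Default 1 for probability weights and 0 otherwise.  Reported scores always
exclude the penalty; only the internal ranking uses it.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .network import Network

logger = logging.getLogger(__name__)

__all__ = [
    "WeightMode",
    "CostConfig",
    "CostConfigError",
    "CostValidationError",
    "default_edge_penalty",
    "edge_cost",
    "path_score",
    "validate_network_weights",
]


class WeightMode(str, Enum):
    UNWEIGHTED = "unweighted"
    ADDITIVE = "additive"
    PROBABILITY = "probability"


class CostConfigError(ValueError):
    """The cost configuration itself is unusable (e.g. missing weights)."""


class CostValidationError(ValueError):
    """An edge weight lies outside the domain of the selected mode."""


def default_edge_penalty(mode: WeightMode) -> float:
    return 1.0 if mode is WeightMode.PROBABILITY else 0.0


@dataclass(frozen=True)
class CostConfig:
    """Weight mode plus edge penalty; validates the mode's penalty domain."""

    mode: WeightMode = WeightMode.UNWEIGHTED
    edge_penalty: Optional[float] = None

    def __post_init__(self):
        mode = WeightMode(self.mode)
        object.__setattr__(self, "mode", mode)
        penalty = self.edge_penalty
        if penalty is None:
            penalty = default_edge_penalty(mode)
        penalty = float(penalty)
        if not math.isfinite(penalty):
            raise CostConfigError(f"edge penalty must be finite, got {penalty!r}")
        if mode is WeightMode.PROBABILITY and penalty < 1.0:
            raise CostConfigError(
                f"probability mode requires edge penalty >= 1 (multiplicative), got {penalty!r}"
            )
        if penalty < 0.0:
            raise CostConfigError(f"edge penalty must be non-negative, got {penalty!r}")
        object.__setattr__(self, "edge_penalty", penalty)

    @classmethod
    def create(cls, mode, edge_penalty=None) -> "CostConfig":
        """Lenient constructor: an invalid penalty falls back to the mode's
        default with a logged warning (mirrors the interactive app's
        use-the-default behaviour)."""
        mode = WeightMode(mode)
        if edge_penalty is not None:
            try:
                return cls(mode, float(edge_penalty))
            except (TypeError, ValueError, CostConfigError):
                logger.warning(
                    "invalid edge penalty %r for mode %s; using default %s",
                    edge_penalty, mode.value, default_edge_penalty(mode),
                )
        return cls(mode, None)


def edge_cost(weight: Optional[float], config: CostConfig) -> float:
    """Internal additive cost of one edge under ``config``.

    Unweighted edges cost 1 (the penalty is irrelevant without weights).
    """
    if config.mode is WeightMode.UNWEIGHTED:
        return 1.0
    if weight is None:
        raise CostConfigError(f"{config.mode.value} mode requires edge weights")
    if config.mode is WeightMode.ADDITIVE:
        if weight < 0 or not math.isfinite(weight):
            raise CostValidationError(f"additive weight must be >= 0, got {weight!r}")
        return weight + config.edge_penalty
    if not (0.0 < weight <= 1.0):
        raise CostValidationError(f"probability weight must be in (0, 1], got {weight!r}")
    return abs(math.log(weight)) + math.log(config.edge_penalty)


def path_score(nodes: Sequence[str], network: Network, config: CostConfig):
    """User-facing score of a node sequence; excludes the edge penalty.

    Unweighted: edge count.  Additive: sum of raw weights.  Probability:
    product of raw weights.  Raises ``KeyError`` if a consecutive pair is
    not an edge of the network (contract violation).
    """
    weights = []
    for u, v in zip(nodes, nodes[1:]):
        if (u, v) not in network.edges:
            raise KeyError(f"path step ({u!r}, {v!r}) is not an edge of the network")
        weights.append(network.edges[(u, v)])
    if config.mode is WeightMode.UNWEIGHTED:
        return len(nodes) - 1
    if any(w is None for w in weights):
        raise CostConfigError(f"{config.mode.value} mode requires edge weights")
    if config.mode is WeightMode.ADDITIVE:
        return float(sum(weights))
    product = 1.0
    for w in weights:
        product *= w
    return product


def validate_network_weights(network: Network, config: CostConfig) -> None:
    """Check every edge weight against the mode's domain before any search."""
    for (u, v), w in network.edges.items():
        if config.mode is WeightMode.UNWEIGHTED:
            continue
        if w is None:
            raise CostConfigError(
                f"{config.mode.value} mode requires edge weights, "
                f"but edge ({u!r}, {v!r}) has none"
            )
        if config.mode is WeightMode.ADDITIVE and w < 0:
            raise CostValidationError(f"edge ({u!r}, {v!r}): negative additive weight {w!r}")
        if config.mode is WeightMode.PROBABILITY and not (0.0 < w <= 1.0):
            raise CostValidationError(
                f"edge ({u!r}, {v!r}): weight {w!r} is not a probability in (0, 1]"
            )
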