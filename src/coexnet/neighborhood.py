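"""Bait-centered k-step neighborhood extraction.

A pathway network for one species is defined as the induced subgraph on
all genes within ``steps`` hops (unweighted shortest-path distance) of any
bait gene.  Multiple baits are treated as a single multi-source search:
the distance of a gene is the minimum over baits.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import NamedTuple

import networkx as nx

from coexnet.io import GeneNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class BaitSet:
    """Query genes seeding the neighborhood search for one species."""

    species_id: str
    baits: frozenset[str]

    def __post_init__(self) -> None:
        if not self.baits:
            raise ValueError("bait set must be non-empty")


class NeighborhoodResult(NamedTuple):
    """Extracted subnetwork plus the baits that were not found."""

    network: GeneNetwork
    missing_baits: frozenset[str]


def extract_neighborhood(
    net: GeneNetwork, baits: BaitSet, steps: int = 2
) -> NeighborhoodResult:
    """Induced subgraph on genes within ``steps`` hops of any bait.

    Baits absent from the network are reported in the result, not silently
    dropped; if no bait is present at all, that is an error.

    Parameters
    ----------
    net
        Source gene network.
    baits
        Query genes; distance is the minimum hop count over all present
        baits (multi-source breadth-first search).
    steps
        Maximum hop distance; ``steps=0`` keeps exactly the present baits
        and any edges among them.

    Returns
    -------
    NeighborhoodResult
        ``network`` is the induced subgraph (all original edges among kept
        nodes); ``missing_baits`` lists baits absent from ``net``.
    """
    if steps < 0:
        raise ValueError(f"steps must be non-negative, got {steps}")
    present = baits.baits & set(net.graph.nodes)
    missing = frozenset(baits.baits - present)
    if not present:
        raise ValueError(
            f"none of the {len(baits.baits)} baits are present in network "
            f"{net.species_id!r}"
        )
    if missing:
        logger.warning(
            "network %s: %d bait(s) not found: %s",
            net.species_id,
            len(missing),
            ", ".join(sorted(missing)),
        )
    keep: set[str] = set()
    for depth, layer in enumerate(nx.bfs_layers(net.graph, sorted(present))):
        if depth > steps:
            break
        keep.update(layer)
    sub = net.graph.subgraph(keep).copy()
    return NeighborhoodResult(GeneNetwork(net.species_id, sub), missing)
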