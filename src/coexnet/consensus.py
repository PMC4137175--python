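"""Family-level collapse of gene networks and cross-species consensus.

Collapsing: a family node exists iff the gene network contains at least
one mapped gene of that family; an edge (f, g) with f != g exists iff any
gene of f is adjacent to any gene of g; a self-loop (f, f) exists iff two
distinct genes of f are adjacent (intra-family co-expression).

Consensus: nodes are families whose conservation count meets
``min_node_support``; edges are family pairs present in at least
``min_edge_support`` of the per-species family networks, restricted to
retained nodes.  Supports count networks, never gene-pair multiplicity
within a network.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from coexnet.conservation import ConservationProfile
from coexnet.io import UNASSIGNED, FamilyMap, GeneNetwork, _canonical_edge


@dataclass
class FamilyNetwork:
    """One species' network collapsed to family identifiers; self-loops
    mark intra-family co-expression."""

    species_id: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {_canonical_edge(a, b) for a, b in self.graph.edges}


@dataclass
class ConsensusNetwork:
    """Cross-species family graph; nodes carry ``support`` = conservation
    count, edges carry ``support`` = number of species family-networks
    containing the edge."""

    graph: nx.Graph = field(default_factory=nx.Graph)
    n_networks: int = 0

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {_canonical_edge(a, b) for a, b in self.graph.edges}

    def node_support(self, family: str) -> int:
        return self.graph.nodes[family]["support"]

    def edge_support(self, a: str, b: str) -> int:
        return self.graph.edges[a, b]["support"]


def collapse_to_family_graph(net: GeneNetwork, fam: FamilyMap) -> FamilyNetwork:
    """Collapse a gene network to its family-level graph.

    Unmapped (:data:`~coexnet.io.UNASSIGNED`) genes are excluded entirely.
    """
    g = nx.Graph()
    for gene in net.graph.nodes:
        family = fam.family_of(gene)
        if family != UNASSIGNED:
            g.add_node(family)
    for a, b in net.graph.edges:
        fa, fb = fam.family_of(a), fam.family_of(b)
        if fa == UNASSIGNED or fb == UNASSIGNED:
            continue
        # fa == fb yields the intra-family self-loop: a != b is guaranteed
        # by the gene-network invariant, so two distinct genes are adjacent
        g.add_edge(fa, fb)
    return FamilyNetwork(net.species_id, g)


def build_consensus(
    family_nets: Sequence[FamilyNetwork],
    profile: ConservationProfile,
    min_node_support: int = 3,
    min_edge_support: int = 3,
) -> ConsensusNetwork:
    """Combine per-species family networks, retaining only supported
    families and relationships.

    Raises if either threshold falls outside [1, S] where S is the number
    of family networks.  The result is invariant to input order and
    monotone in both thresholds (raising one never adds nodes or edges).
    """
    if not family_nets:
        raise ValueError("need at least one family network")
    s = len(family_nets)
    for name, value in (("min_node_support", min_node_support), ("min_edge_support", min_edge_support)):
        if not 1 <= value <= s:
            raise ValueError(f"{name} must be in [1, {s}], got {value}")
    edge_occurrence: Counter[tuple[str, str]] = Counter()
    for fnet in family_nets:
        edge_occurrence.update(fnet.edges)
    g = nx.Graph()
    retained = {f for f, c in profile.counts.items() if c >= min_node_support}
    # sorted insertion keeps serialized output stable across processes
    for family in sorted(retained):
        g.add_node(family, support=profile.counts[family])
    for (a, b), occ in sorted(edge_occurrence.items()):
        if occ >= min_edge_support and a in retained and b in retained:
            g.add_edge(a, b, support=occ)
    return ConsensusNetwork(g, n_networks=s)
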