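"""Gene-family conservation scoring across species networks.

A family's conservation count is the number of input networks containing
at least one gene mapped to it — multiplicity within a network is ignored
(a family with many genes in one network still counts once for that
network).  Genes whose family is unmapped get conservation class 0.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Mapping, Sequence

from coexnet.io import UNASSIGNED, FamilyMap, GeneNetwork


@dataclass(frozen=True)
class ConservationProfile:
    """family identifier -> number of networks containing >=1 of its genes.

    ``n_networks`` is the number of networks compared (S); counts lie in
    [1, S] and families absent from every network are not listed.  The
    reserved :data:`~coexnet.io.UNASSIGNED` label never appears as a key.
    """

    counts: Mapping[str, int]
    n_networks: int

    def __post_init__(self) -> None:
        if UNASSIGNED in self.counts:
            raise ValueError(f"{UNASSIGNED!r} must not appear in a conservation profile")
        for fam, c in self.counts.items():
            if not 1 <= c <= self.n_networks:
                raise ValueError(
                    f"count {c} for family {fam!r} outside [1, {self.n_networks}]"
                )

    def count_of(self, family: str) -> int:
        """Conservation count of *family*; 0 if absent or unassigned."""
        if family == UNASSIGNED:
            return 0
        return self.counts.get(family, 0)


@dataclass
class LabeledNetwork(GeneNetwork):
    """A gene network whose nodes carry ``family`` and
    ``conservation_class`` attributes (class 0 = unassigned family).

    ``n_networks`` records the S of the profile used to label it.
    """

    n_networks: int = 0

    def family_of(self, gene: str) -> str:
        return self.graph.nodes[gene]["family"]

    def class_of(self, gene: str) -> int:
        return self.graph.nodes[gene]["conservation_class"]


def conservation_profile(
    networks: Sequence[GeneNetwork], fam: FamilyMap
) -> ConservationProfile:
    """Count, per family, the number of networks it occurs in.

    Networks must carry distinct ``species_id`` labels.  The result is
    invariant to input order.
    """
    if not networks:
        raise ValueError("need at least one network")
    ids = [n.species_id for n in networks]
    if len(set(ids)) != len(ids):
        raise ValueError(f"networks must have distinct species_ids, got {ids}")
    counts: Counter[str] = Counter()
    for net in networks:
        families_here = {
            fam.family_of(g) for g in net.graph.nodes if fam.family_of(g) != UNASSIGNED
        }
        counts.update(sorted(families_here))
    return ConservationProfile(dict(counts), n_networks=len(networks))


def label_network(
    net: GeneNetwork, fam: FamilyMap, profile: ConservationProfile
) -> LabeledNetwork:
    """Annotate every node with its family and conservation class."""
    labeled = LabeledNetwork(net.species_id, net.graph.copy(), profile.n_networks)
    for gene in labeled.graph.nodes:
        family = fam.family_of(gene)
        labeled.graph.nodes[gene]["family"] = family
        labeled.graph.nodes[gene]["conservation_class"] = profile.count_of(family)
    return labeled


def conserved_core(net: LabeledNetwork, min_networks: int) -> LabeledNetwork:
    """Induced subgraph on nodes with conservation_class >= min_networks."""
    if min_networks < 1 or (net.n_networks and min_networks > net.n_networks):
        raise ValueError(
            f"min_networks must be in [1, {net.n_networks or 'S'}], got {min_networks}"
        )
    keep = {
        g for g, d in net.graph.nodes(data=True) if d["conservation_class"] >= min_networks
    }
    return LabeledNetwork(net.species_id, net.graph.subgraph(keep).copy(), net.n_networks)


def class_distribution(net: LabeledNetwork) -> dict[int, int]:
    """Histogram of conservation classes; values sum to the node count."""
    hist: Counter[int] = Counter(
        d["conservation_class"] for _, d in net.graph.nodes(data=True)
    )
    return dict(sorted(hist.items()))
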