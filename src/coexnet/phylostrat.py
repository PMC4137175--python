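"""First-appearance (phylostratum) assignment and consensus annotation.

A family's stratum is the oldest clade (lowest index in the ordered clade
list) in which it is recorded present.  Non-contiguous presence
(present, absent, present) is read as origin at the oldest presence with a
later loss — a single-origin assumption.  Clade order is user-supplied;
no phylogeny is inferred.
"""

from __future__ import annotations

from collections import Counter

from coexnet.consensus import ConsensusNetwork
from coexnet.io import LineageTable

#: Stratum for families whose presence vector is all-false.
ABSENT = "ABSENT"
#: Stratum for consensus families missing from the assignment entirely.
UNKNOWN = "UNKNOWN"


def first_appearance(lineage: LineageTable) -> dict[str, str]:
    """Map each family to the oldest clade where it is present, or
    :data:`ABSENT` if it is present nowhere."""
    strata: dict[str, str] = {}
    for family, vec in lineage.presence.items():
        strata[family] = ABSENT
        for clade, present in zip(lineage.clades, vec):
            if present:
                strata[family] = clade
                break
    return strata


def annotate_strata(
    consensus: ConsensusNetwork, strata: dict[str, str]
) -> ConsensusNetwork:
    """Return a copy of the consensus with a ``stratum`` attribute on every
    node; families not covered by *strata* get :data:`UNKNOWN`."""
    annotated = ConsensusNetwork(consensus.graph.copy(), consensus.n_networks)
    for family in annotated.graph.nodes:
        annotated.graph.nodes[family]["stratum"] = strata.get(family, UNKNOWN)
    return annotated


def stratum_summary(consensus: ConsensusNetwork) -> dict[str, int]:
    """Stratum -> family count over an annotated consensus; counts sum to
    the consensus node count."""
    hist: Counter[str] = Counter(
        d.get("stratum", UNKNOWN) for _, d in consensus.graph.nodes(data=True)
    )
    return dict(sorted(hist.items()))
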