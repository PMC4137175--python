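"""Annotation composition per conservation class.

Each gene is classified into exactly one category with precedence
target > unknown > other:

* ``target``  — any of its bins falls in the target set (e.g. "10");
* ``unknown`` — otherwise, any bin falls in the unknown set (e.g. "35");
* ``other``   — everything else, including genes with no annotation record.

Bin matching is on the top-level code: a hierarchical bin like "10.2.1"
matches target "10" via its prefix before the first dot.
"""

from __future__ import annotations

from collections import Counter
from typing import Iterable, Sequence

import pandas as pd

from coexnet.conservation import LabeledNetwork
from coexnet.io import AnnotationTable

CATEGORIES = ("target", "unknown", "other")


def _top_level(bin_code: str) -> str:
    return bin_code.split(".", 1)[0]


def classify_gene(
    bins: Iterable[str], target_bins: frozenset[str], unknown_bins: frozenset[str]
) -> str:
    tops = {_top_level(b) for b in bins}
    if tops & target_bins:
        return "target"
    if tops & unknown_bins:
        return "unknown"
    return "other"


def tally_by_class(
    nets: Sequence[LabeledNetwork],
    ann: AnnotationTable,
    target_bins: Iterable[str],
    unknown_bins: Iterable[str],
    dedupe: bool = False,
) -> pd.DataFrame:
    """Tally gene categories per conservation class across networks.

    By default a gene appearing in several networks is counted once per
    network; with ``dedupe=True`` it is counted once overall.

    Returns
    -------
    pandas.DataFrame
        Columns ``conservation_class``, ``category``, ``gene_count``; for
        each class the three category counts sum to the number of genes in
        that class.
    """
    target = frozenset(_top_level(b) for b in target_bins)
    unknown = frozenset(_top_level(b) for b in unknown_bins)
    overlap = target & unknown
    if overlap:
        raise ValueError(f"target and unknown bin sets overlap: {sorted(overlap)}")
    counts: Counter[tuple[int, str]] = Counter()
    seen: set[str] = set()
    for net in nets:
        for gene, data in net.graph.nodes(data=True):
            if dedupe:
                if gene in seen:
                    continue
                seen.add(gene)
            category = classify_gene(ann.bins_of(gene), target, unknown)
            counts[(data["conservation_class"], category)] += 1
    classes = sorted({cls for cls, _ in counts})
    rows = [
        {
            "conservation_class": cls,
            "category": cat,
            "gene_count": counts.get((cls, cat), 0),
        }
        for cls in classes
        for cat in CATEGORIES
    ]
    return pd.DataFrame(rows, columns=["conservation_class", "category", "gene_count"])
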