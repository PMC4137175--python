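"""Synthetic multi-species bundles with a planted conserved core.

The generator emulates the statistical structure the comparative analysis
relies on: a set of core families whose genes are mutually co-expressed in
every species, surrounded by species-specific noise genes and edges.

Draw order (one ``random.Random(seed)`` stream, so results are
reproducible and the order is part of the contract):

1. per species, in species order:
   a. one Bernoulli(core_edge_prob) per unordered pair of core genes,
      pairs enumerated in sorted order;
   b. repair edges (deterministic, no draws) connecting any core family
      left farther than two steps from the bait family's genes;
   c. per noise gene, in index order, one Bernoulli(noise_edge_prob) per
      pre-existing node, nodes in insertion order;
2. per core gene, species order then family order then gene index: one
   uniform draw for the annotation bin (target "10" w.p. 0.9, else "35");
3. per noise gene, same ordering: one uniform choice among other bins;
4. per core family, in family order: one weighted stratum draw.

Noise genes each get their own species-specific family, so noise families
can never co-occur across networks (expected conservation count 1).
"""

from __future__ import annotations

import logging
import random
from collections import deque
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from coexnet.io import (
    AnnotationTable,
    FamilyMap,
    GeneNetwork,
    LineageTable,
    write_annotation,
    write_family_map,
    write_lineage_table,
    write_network,
)

logger = logging.getLogger(__name__)

TARGET_BIN = "10"
UNKNOWN_BIN = "35"
OTHER_BINS = ("20", "26", "29", "33")
TARGET_BIN_PROB = 0.9

DEFAULT_CLADES = ("chlorophytes", "mosses", "angiosperms")


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameters for one synthetic bundle; validated on construction."""

    n_species: int = 4
    n_core_families: int = 20
    genes_per_family: int = 2
    n_noise_genes_per_species: int = 200
    core_edge_prob: float = 0.3
    noise_edge_prob: float = 0.01
    bait_family: str | None = None
    seed: int = 0
    clades: tuple[str, ...] = DEFAULT_CLADES
    core_stratum_weights: tuple[float, ...] = (0.5, 0.4, 0.1)

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise ValueError("n_species must be >= 2 (a comparison needs species)")
        if self.n_core_families < 1:
            raise ValueError("need at least one core family (the bait family)")
        if self.genes_per_family < 1:
            raise ValueError("genes_per_family must be >= 1")
        if self.n_noise_genes_per_species < 0:
            raise ValueError("n_noise_genes_per_species must be >= 0")
        if not 0 < self.core_edge_prob <= 1:
            raise ValueError("core_edge_prob must be in (0, 1]")
        if not 0 <= self.noise_edge_prob < 1:
            raise ValueError("noise_edge_prob must be in [0, 1)")
        if len(self.core_stratum_weights) != len(self.clades):
            raise ValueError("core_stratum_weights must align with clades")
        if abs(sum(self.core_stratum_weights) - 1.0) > 1e-9:
            raise ValueError("core_stratum_weights must sum to 1")
        if self.bait_family is not None and self.bait_family not in self.core_family_ids():
            raise ValueError(
                f"bait_family {self.bait_family!r} is not one of the core families"
            )

    def core_family_ids(self) -> tuple[str, ...]:
        return tuple(f"CORE{i:04d}" for i in range(1, self.n_core_families + 1))

    def species_ids(self) -> tuple[str, ...]:
        return tuple(f"sp{i}" for i in range(1, self.n_species + 1))

    @property
    def resolved_bait_family(self) -> str:
        return self.bait_family or self.core_family_ids()[0]


@dataclass
class SyntheticBundle:
    """Everything a pipeline run needs, plus the planted ground truth."""

    networks: list[GeneNetwork]
    family_map: FamilyMap
    annotation: AnnotationTable
    lineage: LineageTable
    ground_truth: dict
    repairs: list[tuple[str, str, str]] = field(default_factory=list)


def _distances_within(graph: nx.Graph, sources: Sequence[str], cutoff: int) -> set[str]:
    """Nodes within *cutoff* hops of any source (plain BFS)."""
    seen = {s: 0 for s in sources if s in graph}
    queue = deque(seen)
    while queue:
        node = queue.popleft()
        if seen[node] == cutoff:
            continue
        for nbr in graph.neighbors(node):
            if nbr not in seen:
                seen[nbr] = seen[node] + 1
                queue.append(nbr)
    return set(seen)


def generate(spec: SyntheticSpec) -> SyntheticBundle:
    """Generate one deterministic bundle from *spec* (see module docstring
    for the draw order)."""
    rng = random.Random(spec.seed)
    core_families = spec.core_family_ids()
    bait_family = spec.resolved_bait_family
    species = spec.species_ids()

    family_entries: dict[str, str] = {}
    networks: list[GeneNetwork] = []
    repairs: list[tuple[str, str, str]] = []
    bait_genes: dict[str, list[str]] = {}
    core_genes_by_species: dict[str, list[str]] = {}
    noise_genes_by_species: dict[str, list[str]] = {}

    for sp in species:
        graph = nx.Graph()
        core_genes: list[str] = []
        genes_of_family: dict[str, list[str]] = {}
        for fam in core_families:
            members = [f"{sp}_{fam}_g{k}" for k in range(spec.genes_per_family)]
            genes_of_family[fam] = members
            for gene in members:
                family_entries[gene] = fam
                graph.add_node(gene)
            core_genes.extend(members)
        core_genes_by_species[sp] = core_genes
        bait_genes[sp] = list(genes_of_family[bait_family])

        # 1a. independent core-core edges, sorted pair enumeration
        ordered = sorted(core_genes)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                if rng.random() < spec.core_edge_prob:
                    graph.add_edge(a, b)

        # 1b. repair: every core family must sit within two steps of the
        # bait genes so neighborhood extraction can recover the full core
        reachable = _distances_within(graph, bait_genes[sp], cutoff=2)
        for fam in core_families:
            if not any(g in reachable for g in genes_of_family[fam]):
                a, b = genes_of_family[fam][0], bait_genes[sp][0]
                if a != b:
                    graph.add_edge(a, b)
                    repairs.append((sp, a, b))
                    logger.info("repair: %s connected %s to bait gene %s", sp, a, b)
                    reachable = _distances_within(graph, bait_genes[sp], cutoff=2)

        # 1c. noise genes, each attached independently to pre-existing nodes
        noise_genes: list[str] = []
        anchor_order = list(core_genes)
        for k in range(spec.n_noise_genes_per_species):
            gene = f"{sp}_noise{k:04d}"
            family_entries[gene] = f"{sp.upper()}NOISE{k:04d}"
            graph.add_node(gene)
            for anchor in anchor_order:
                if rng.random() < spec.noise_edge_prob:
                    graph.add_edge(gene, anchor)
            anchor_order.append(gene)
            noise_genes.append(gene)
        noise_genes_by_species[sp] = noise_genes
        networks.append(GeneNetwork(sp, graph))

    # 2. core gene annotation
    ann_entries: dict[str, set[str]] = {}
    for sp in species:
        for gene in core_genes_by_species[sp]:
            bin_code = TARGET_BIN if rng.random() < TARGET_BIN_PROB else UNKNOWN_BIN
            ann_entries.setdefault(gene, set()).add(bin_code)
    # 3. noise gene annotation
    for sp in species:
        for gene in noise_genes_by_species[sp]:
            ann_entries.setdefault(gene, set()).add(rng.choice(OTHER_BINS))

    # 4. lineage table: core families appear at a sampled stratum and stay;
    # noise families appear only in the newest clade
    n_clades = len(spec.clades)
    presence: dict[str, tuple[bool, ...]] = {}
    strata_truth: dict[str, str] = {}
    for fam in core_families:
        idx = rng.choices(range(n_clades), weights=spec.core_stratum_weights, k=1)[0]
        presence[fam] = tuple(i >= idx for i in range(n_clades))
        strata_truth[fam] = spec.clades[idx]
    newest = spec.clades[-1]
    for sp in species:
        for gene in noise_genes_by_species[sp]:
            fam = family_entries[gene]
            presence[fam] = tuple(i == n_clades - 1 for i in range(n_clades))
            strata_truth[fam] = newest

    ground_truth = {
        "core_families": list(core_families),
        "bait_family": bait_family,
        "bait_genes": bait_genes,
        "strata": strata_truth,
        "seed": spec.seed,
    }
    return SyntheticBundle(
        networks=networks,
        family_map=FamilyMap(family_entries),
        annotation=AnnotationTable({g: frozenset(b) for g, b in ann_entries.items()}),
        lineage=LineageTable(clades=spec.clades, presence=presence),
        ground_truth=ground_truth,
        repairs=repairs,
    )


def write_bundle(bundle: SyntheticBundle, outdir: str | Path) -> dict[str, str]:
    """Write the bundle as the TSV formats the readers consume plus
    ``ground_truth.json``; returns a name -> path map.  Output is
    deterministic (sorted writers), so identical seeds give byte-identical
    files."""
    import json

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, str] = {}
    for net in bundle.networks:
        p = outdir / f"network_{net.species_id}.tsv"
        write_network(net, p, format="edge_tsv")
        paths[f"network_{net.species_id}"] = str(p)
    write_family_map(bundle.family_map, outdir / "families.tsv")
    paths["families"] = str(outdir / "families.tsv")
    write_annotation(bundle.annotation, outdir / "annotation.tsv")
    paths["annotation"] = str(outdir / "annotation.tsv")
    write_lineage_table(bundle.lineage, outdir / "lineage.tsv")
    paths["lineage"] = str(outdir / "lineage.tsv")
    gt_path = outdir / "ground_truth.json"
    with open(gt_path, "w", encoding="utf-8") as fh:
        json.dump(bundle.ground_truth, fh, indent=2, sort_keys=True)
        fh.write("\n")
    paths["ground_truth"] = str(gt_path)
    baits_dir = outdir / "baits"
    baits_dir.mkdir(exist_ok=True)
    for sp, genes in bundle.ground_truth["bait_genes"].items():
        p = baits_dir / f"baits_{sp}.txt"
        with open(p, "w", encoding="utf-8") as fh:
            for g in sorted(genes):
                fh.write(g + "\n")
        paths[f"baits_{sp}"] = str(p)
    return paths
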