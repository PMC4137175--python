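"""Readers and writers for the file formats the pipeline touches.

Formats
-------
Edge list
    TSV with columns ``gene_a<TAB>gene_b``; lines starting with ``#`` are
    skipped.  A one-column line declares a singleton node (a bait may have
    no neighbors).  An optional third column (e.g. an edge weight from an
    upstream tool) is ignored with a logged note: the analysis uses
    topology only.
Family map
    TSV ``gene<TAB>family`` (PLAZA-style, e.g. ``HOM000082``); many genes
    may share one family but each gene maps to at most one family.
Annotation
    TSV ``gene<TAB>bin`` (Mapman-style); multiple rows per gene allowed.
Lineage table
    TSV whose header lists clade labels oldest-first; each row is a family
    followed by 0/1 presence flags, one per clade.

Gene identifiers are case-sensitive opaque strings; no cross-species
normalization is attempted (orthology is expressed only through shared
family identifiers).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx

logger = logging.getLogger(__name__)

#: Reserved family label for genes absent from the family map.  Such genes
#: are retained in networks but never contribute to conservation counts.
UNASSIGNED = "UNASSIGNED"


class ParseError(ValueError):
    """Raised for malformed input files; the message names the offending
    line number or key."""


def _canonical_edge(a: str, b: str) -> tuple[str, str]:
    """Canonical unordered representation of an edge."""
    return (a, b) if a <= b else (b, a)


@dataclass
class GeneNetwork:
    """One species' undirected co-expression graph (genes as nodes).

    Invariants: no self-edges, edges are unordered and deduplicated, and
    every edge endpoint is a member of the node set.  Backed by a
    :class:`networkx.Graph`; node attributes (``family``,
    ``conservation_class``) may be attached by downstream stages.
    """

    species_id: str
    graph: nx.Graph = field(default_factory=nx.Graph)

    @property
    def nodes(self) -> set[str]:
        return set(self.graph.nodes)

    @property
    def edges(self) -> set[tuple[str, str]]:
        return {_canonical_edge(a, b) for a, b in self.graph.edges}

    def add_node(self, gene: str) -> None:
        self.graph.add_node(gene)

    def add_edge(self, a: str, b: str) -> None:
        if a == b:
            raise ValueError(f"self-edge on gene {a!r} is not allowed")
        self.graph.add_edge(a, b)

    def number_of_nodes(self) -> int:
        return self.graph.number_of_nodes()

    def number_of_edges(self) -> int:
        return self.graph.number_of_edges()

    def copy(self) -> "GeneNetwork":
        return type(self)(self.species_id, self.graph.copy())


@dataclass(frozen=True)
class FamilyMap:
    """Many-to-one mapping from gene identifier to family identifier."""

    entries: Mapping[str, str]

    def __post_init__(self) -> None:
        for gene, fam in self.entries.items():
            if not fam:
                raise ValueError(f"empty family identifier for gene {gene!r}")

    def family_of(self, gene: str) -> str:
        """Family of *gene*, or :data:`UNASSIGNED` if unmapped."""
        return self.entries.get(gene, UNASSIGNED)

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, gene: str) -> bool:
        return gene in self.entries


@dataclass(frozen=True)
class AnnotationTable:
    """Gene identifier -> set of ontology bin codes (opaque strings)."""

    entries: Mapping[str, frozenset[str]]

    def bins_of(self, gene: str) -> frozenset[str]:
        return self.entries.get(gene, frozenset())

    def __len__(self) -> int:
        return len(self.entries)


@dataclass(frozen=True)
class LineageTable:
    """Ordered clades (oldest first) x family presence/absence."""

    clades: tuple[str, ...]
    presence: Mapping[str, tuple[bool, ...]]

    def __post_init__(self) -> None:
        if not self.clades:
            raise ValueError("lineage table needs at least one clade")
        if len(set(self.clades)) != len(self.clades):
            raise ValueError("clade labels must be unique")
        for fam, vec in self.presence.items():
            if len(vec) != len(self.clades):
                raise ValueError(
                    f"presence vector for family {fam!r} has {len(vec)} entries, "
                    f"expected {len(self.clades)}"
                )

    @property
    def families(self) -> set[str]:
        return set(self.presence)


def read_edge_list(path: str | Path, species_id: str) -> GeneNetwork:
    """Read a TSV edge list into a :class:`GeneNetwork`.

    Self-edges are dropped with a warning (not an error); duplicated edges,
    in either orientation, collapse to one.  One-column lines declare
    singleton nodes.  A third column is ignored with a logged note.

    Raises
    ------
    ParseError
        On lines with zero or more than three fields, naming the line.
    """
    net = GeneNetwork(species_id)
    weight_note_logged = False
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (1, 2, 3):
                raise ParseError(
                    f"{path}: line {lineno}: expected 1-3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            if any(not f.strip() for f in fields[: min(len(fields), 2)]):
                raise ParseError(f"{path}: line {lineno}: empty gene identifier")
            if len(fields) == 1:
                net.add_node(fields[0].strip())
                continue
            if len(fields) == 3 and not weight_note_logged:
                logger.info(
                    "%s: third column present; ignored (networks are unweighted)", path
                )
                weight_note_logged = True
            a, b = fields[0].strip(), fields[1].strip()
            if a == b:
                logger.warning("%s: line %d: self-edge on %r dropped", path, lineno, a)
                net.add_node(a)
                continue
            net.add_edge(a, b)
    return net


def read_family_map(path: str | Path) -> FamilyMap:
    """Read a ``gene<TAB>family`` TSV.

    Duplicate identical rows are deduplicated silently; a gene listed with
    two different families is an error naming the gene.
    """
    entries: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 fields, got {len(fields)}"
                )
            gene, fam = fields[0].strip(), fields[1].strip()
            if not gene or not fam:
                raise ParseError(f"{path}: line {lineno}: empty gene or family field")
            if gene in entries and entries[gene] != fam:
                raise ParseError(
                    f"{path}: gene {gene!r} mapped to conflicting families "
                    f"{entries[gene]!r} and {fam!r}"
                )
            entries[gene] = fam
    return FamilyMap(entries)


def read_annotation(path: str | Path) -> AnnotationTable:
    """Read a ``gene<TAB>bin`` TSV into an :class:`AnnotationTable`."""
    entries: dict[str, set[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ParseError(
                    f"{path}: line {lineno}: expected 2 fields, got {len(fields)}"
                )
            gene, bin_code = fields[0].strip(), fields[1].strip()
            if not bin_code:
                raise ParseError(f"{path}: line {lineno}: empty bin field")
            if not gene:
                raise ParseError(f"{path}: line {lineno}: empty gene field")
            entries.setdefault(gene, set()).add(bin_code)
    return AnnotationTable({g: frozenset(b) for g, b in entries.items()})


def read_lineage_table(path: str | Path) -> LineageTable:
    """Read a lineage TSV: header row of clade labels (oldest first), then
    one row per family with 0/1 presence flags."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n")
        if not header.strip():
            raise ParseError(f"{path}: missing header line")
        cols = header.lstrip("#").split("\t")
        clades = tuple(c.strip() for c in cols[1:])
        if not clades:
            raise ParseError(f"{path}: header lists no clades")
        presence: dict[str, tuple[bool, ...]] = {}
        for lineno, raw in enumerate(fh, start=2):
            line = raw.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            fam = fields[0].strip()
            cells = fields[1:]
            if len(cells) != len(clades):
                raise ParseError(
                    f"{path}: family {fam!r}: row has {len(cells)} presence cells, "
                    f"expected {len(clades)}"
                )
            vec = []
            for cell in cells:
                cell = cell.strip()
                if cell not in ("0", "1"):
                    raise ParseError(
                        f"{path}: family {fam!r}: presence cell {cell!r} is not 0/1"
                    )
                vec.append(cell == "1")
            presence[fam] = tuple(vec)
    return LineageTable(clades=clades, presence=presence)


def write_lineage_table(table: LineageTable, path: str | Path) -> None:
    """Write a :class:`LineageTable` in the format :func:`read_lineage_table`
    reads (round-trip safe)."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("family\t" + "\t".join(table.clades) + "\n")
        for fam in sorted(table.presence):
            flags = "\t".join("1" if p else "0" for p in table.presence[fam])
            fh.write(f"{fam}\t{flags}\n")


def write_family_map(fam: FamilyMap, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(fam.entries):
            fh.write(f"{gene}\t{fam.entries[gene]}\n")


def write_annotation(ann: AnnotationTable, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for gene in sorted(ann.entries):
            for bin_code in sorted(ann.entries[gene]):
                fh.write(f"{gene}\t{bin_code}\n")


def _graph_of(net) -> nx.Graph:
    return net.graph


def write_network(net, path: str | Path, format: str = "edge_tsv") -> None:
    """Write a gene or consensus network.

    ``edge_tsv``: sorted two-column edge lines plus one-column lines for
    isolated nodes; reading the file back reproduces the node and edge sets
    exactly.  Consensus networks gain a third ``support`` column (ignored
    on re-read).

    ``graphml``: node attributes (``family``, ``conservation_class``,
    ``stratum``, ``support``) and the edge ``support`` attribute are
    emitted where present.
    """
    g = _graph_of(net)
    if format == "edge_tsv":
        with open(path, "w", encoding="utf-8") as fh:
            fh.write("#gene_a\tgene_b\n")
            for a, b in sorted(_canonical_edge(a, b) for a, b in g.edges):
                support = g.edges[a, b].get("support")
                if support is not None:
                    fh.write(f"{a}\t{b}\t{support}\n")
                else:
                    fh.write(f"{a}\t{b}\n")
            for node in sorted(n for n in g.nodes if g.degree(n) == 0):
                fh.write(f"{node}\n")
    elif format == "graphml":
        nx.write_graphml(g, path, named_key_ids=True)
    else:
        raise ValueError(f"unknown network format {format!r}")
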