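"""End-to-end orchestration: extract -> conserve -> consensus -> phylo ->
relevance, driven by a single YAML config.

Outputs per run (under ``output_dir``):

* ``neighborhood_<species>.tsv`` and ``labeled_<species>.graphml``
* ``conservation_profile.tsv`` — family, count, member genes per network
* ``class_distribution.tsv``
* ``core_<species>.graphml`` — conserved-core subnetworks
* ``consensus.graphml`` — family consensus with supports and strata
* ``strata_summary.tsv`` and ``relevance.tsv``
* ``summary.json`` — gene/family counts per stage

All outputs are deterministic functions of the inputs: rerunning on the
same files yields byte-identical results.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import yaml

from coexnet import consensus as consensus_mod
from coexnet import conservation as conservation_mod
from coexnet import phylostrat, relevance
from coexnet.io import (
    read_annotation,
    read_edge_list,
    read_family_map,
    read_lineage_table,
    write_network,
)
from coexnet.neighborhood import BaitSet, extract_neighborhood

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage."""


@dataclass(frozen=True)
class NetworkEntry:
    path: str
    species_id: str
    baits: tuple[str, ...]


@dataclass(frozen=True)
class PipelineConfig:
    networks: tuple[NetworkEntry, ...]
    family_map: str
    output_dir: str
    annotation: str | None = None
    lineage: str | None = None
    steps: int = 2
    min_networks: int | None = None  # None -> all networks (strictest core)
    min_node_support: int = 3
    min_edge_support: int = 3
    target_bins: tuple[str, ...] = ("10",)
    unknown_bins: tuple[str, ...] = ("35",)
    dedupe: bool = False

    def __post_init__(self) -> None:
        if len(self.networks) < 2:
            raise ValueError(
                f"a comparison needs at least 2 networks, got {len(self.networks)}"
            )
        ids = [n.species_id for n in self.networks]
        if len(set(ids)) != len(ids):
            raise ValueError(f"duplicate species_ids in config: {ids}")


def load_config(path: str | Path) -> PipelineConfig:
    """Load a YAML pipeline config.

    Expected keys: ``networks`` (list of ``{path, species_id, baits}`` where
    ``baits`` is a list of genes or a ``baits_file`` path), ``family_map``,
    ``output_dir``; optional ``annotation``, ``lineage``, ``steps``,
    thresholds, ``target_bins``, ``unknown_bins``, ``dedupe``.
    """
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    base = Path(path).parent

    def _resolve(p: str | None) -> str | None:
        if p is None:
            return None
        q = Path(p)
        return str(q if q.is_absolute() else base / q)

    entries = []
    for item in raw.get("networks", []):
        if "baits_file" in item:
            with open(_resolve(item["baits_file"]), encoding="utf-8") as fh:
                baits = tuple(line.strip() for line in fh if line.strip())
        else:
            baits = tuple(item["baits"])
        entries.append(
            NetworkEntry(
                path=_resolve(item["path"]),
                species_id=item["species_id"],
                baits=baits,
            )
        )
    return PipelineConfig(
        networks=tuple(entries),
        family_map=_resolve(raw["family_map"]),
        output_dir=_resolve(raw["output_dir"]),
        annotation=_resolve(raw.get("annotation")),
        lineage=_resolve(raw.get("lineage")),
        steps=int(raw.get("steps", 2)),
        min_networks=raw.get("min_networks"),
        min_node_support=int(raw.get("min_node_support", 3)),
        min_edge_support=int(raw.get("min_edge_support", 3)),
        target_bins=tuple(str(b) for b in raw.get("target_bins", ["10"])),
        unknown_bins=tuple(str(b) for b in raw.get("unknown_bins", ["35"])),
        dedupe=bool(raw.get("dedupe", False)),
    )


def _stage(name: str):
    """Decorator-free stage guard: re-raise any failure naming the stage."""

    class _Guard:
        def __enter__(self):
            logger.info("stage %s: start", name)
            self.t0 = time.monotonic()
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None:
                raise PipelineError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s: done in %.2fs", name, time.monotonic() - self.t0)
            return False

    return _Guard()


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full workflow; returns the JSON-serializable run summary."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"stages": {}, "outputs": {}, "completed": False}

    with _stage("read"):
        fam = read_family_map(config.family_map)
        raw_nets = [
            read_edge_list(entry.path, entry.species_id) for entry in config.networks
        ]
        summary["stages"]["read"] = {
            "networks": {
                n.species_id: {"genes": n.number_of_nodes(), "edges": n.number_of_edges()}
                for n in raw_nets
            },
            "family_map_entries": len(fam),
        }

    with _stage("extract"):
        neighborhoods = []
        extract_info = {}
        for entry, net in zip(config.networks, raw_nets):
            result = extract_neighborhood(
                net, BaitSet(entry.species_id, frozenset(entry.baits)), config.steps
            )
            neighborhoods.append(result.network)
            p = outdir / f"neighborhood_{entry.species_id}.tsv"
            write_network(result.network, p, format="edge_tsv")
            summary["outputs"][f"neighborhood_{entry.species_id}"] = str(p)
            extract_info[entry.species_id] = {
                "genes": result.network.number_of_nodes(),
                "edges": result.network.number_of_edges(),
                "missing_baits": sorted(result.missing_baits),
            }
        summary["stages"]["extract"] = {"steps": config.steps, "networks": extract_info}

    s = len(neighborhoods)
    min_networks = config.min_networks if config.min_networks is not None else s

    with _stage("conserve"):
        profile = conservation_mod.conservation_profile(neighborhoods, fam)
        labeled = [
            conservation_mod.label_network(n, fam, profile) for n in neighborhoods
        ]
        _write_profile_tsv(profile, labeled, fam, outdir / "conservation_profile.tsv")
        summary["outputs"]["conservation_profile"] = str(outdir / "conservation_profile.tsv")
        dist_rows = {}
        for net in labeled:
            write_network(net, outdir / f"labeled_{net.species_id}.graphml", "graphml")
            summary["outputs"][f"labeled_{net.species_id}"] = str(
                outdir / f"labeled_{net.species_id}.graphml"
            )
            dist_rows[net.species_id] = conservation_mod.class_distribution(net)
        _write_class_distribution(dist_rows, outdir / "class_distribution.tsv")
        summary["outputs"]["class_distribution"] = str(outdir / "class_distribution.tsv")
        cores = {}
        for net in labeled:
            core = conservation_mod.conserved_core(net, min_networks)
            write_network(core, outdir / f"core_{net.species_id}.graphml", "graphml")
            summary["outputs"][f"core_{net.species_id}"] = str(
                outdir / f"core_{net.species_id}.graphml"
            )
            cores[net.species_id] = {
                "genes": core.number_of_nodes(),
                "families": len(
                    {d["family"] for _, d in core.graph.nodes(data=True)}
                ),
            }
        core_families = sorted(
            f for f, c in profile.counts.items() if c >= min_networks
        )
        summary["stages"]["conserve"] = {
            "families_total": len(profile.counts),
            "min_networks": min_networks,
            "core_families": len(core_families),
            "class_distribution": {
                sp: {str(k): v for k, v in d.items()} for sp, d in dist_rows.items()
            },
            "cores": cores,
        }

    with _stage("consensus"):
        family_nets = [
            consensus_mod.collapse_to_family_graph(n, fam) for n in neighborhoods
        ]
        cons = consensus_mod.build_consensus(
            family_nets, profile, config.min_node_support, config.min_edge_support
        )
        summary["stages"]["consensus"] = {
            "min_node_support": config.min_node_support,
            "min_edge_support": config.min_edge_support,
            "families": cons.graph.number_of_nodes(),
            "relationships": cons.graph.number_of_edges(),
            "self_loops": sum(1 for a, b in cons.graph.edges if a == b),
        }

    if config.lineage is not None:
        with _stage("phylo"):
            lineage = read_lineage_table(config.lineage)
            strata = phylostrat.first_appearance(lineage)
            cons = phylostrat.annotate_strata(cons, strata)
            strata_counts = phylostrat.stratum_summary(cons)
            with open(outdir / "strata_summary.tsv", "w", encoding="utf-8") as fh:
                fh.write("stratum\tfamilies\n")
                for stratum, count in strata_counts.items():
                    fh.write(f"{stratum}\t{count}\n")
            summary["outputs"]["strata_summary"] = str(outdir / "strata_summary.tsv")
            summary["stages"]["phylo"] = {"strata": strata_counts}

    write_network(cons, outdir / "consensus.graphml", "graphml")
    summary["outputs"]["consensus"] = str(outdir / "consensus.graphml")

    if config.annotation is not None:
        with _stage("relevance"):
            ann = read_annotation(config.annotation)
            table = relevance.tally_by_class(
                labeled, ann, config.target_bins, config.unknown_bins, config.dedupe
            )
            table.to_csv(outdir / "relevance.tsv", sep="\t", index=False)
            summary["outputs"]["relevance"] = str(outdir / "relevance.tsv")
            summary["stages"]["relevance"] = {
                "rows": int(len(table)),
                "genes_counted": int(table["gene_count"].sum()),
            }

    summary["completed"] = True
    # on disk, output paths are relative to the run directory so identical
    # inputs give byte-identical summaries regardless of where the run lives
    on_disk = dict(summary)
    on_disk["outputs"] = {
        k: str(Path(v).relative_to(outdir)) for k, v in summary["outputs"].items()
    }
    with open(outdir / "summary.json", "w", encoding="utf-8") as fh:
        json.dump(on_disk, fh, indent=2, sort_keys=True)
        fh.write("\n")
    summary["outputs"]["summary"] = str(outdir / "summary.json")
    return summary


def _write_profile_tsv(profile, labeled_nets, fam, path: Path) -> None:
    """Conservation report: family, count, then member genes per network,
    sorted by descending count then family id."""
    species = [n.species_id for n in labeled_nets]
    members: dict[str, dict[str, list[str]]] = {}
    for net in labeled_nets:
        for gene, data in net.graph.nodes(data=True):
            family = data["family"]
            if family in profile.counts:
                members.setdefault(family, {}).setdefault(net.species_id, []).append(gene)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("family\tnetworks_present\t" + "\t".join(species) + "\n")
        ordered = sorted(profile.counts, key=lambda f: (-profile.counts[f], f))
        for family in ordered:
            per_sp = [
                ",".join(sorted(members.get(family, {}).get(sp, []))) for sp in species
            ]
            fh.write(f"{family}\t{profile.counts[family]}\t" + "\t".join(per_sp) + "\n")


def _write_class_distribution(dist_rows: dict[str, dict[int, int]], path: Path) -> None:
    classes = sorted({c for d in dist_rows.values() for c in d})
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("species\t" + "\t".join(f"class_{c}" for c in classes) + "\n")
        for sp in dist_rows:
            fh.write(sp + "\t" + "\t".join(str(dist_rows[sp].get(c, 0)) for c in classes) + "\n")


def summarize(outdir: str | Path) -> str:
    """Human-readable per-stage counts from a finished run directory."""
    path = Path(outdir) / "summary.json"
    if not path.exists():
        raise FileNotFoundError(f"stage summary: no summary.json in {outdir}")
    with open(path, encoding="utf-8") as fh:
        summary = json.load(fh)
    lines = []
    stages = summary.get("stages", {})
    if "read" in stages:
        for sp, info in stages["read"]["networks"].items():
            lines.append(f"network {sp}: {info['genes']} genes, {info['edges']} edges")
    if "extract" in stages:
        for sp, info in stages["extract"]["networks"].items():
            lines.append(
                f"neighborhood {sp} (steps={stages['extract']['steps']}): "
                f"{info['genes']} genes, {info['edges']} edges"
            )
    if "conserve" in stages:
        c = stages["conserve"]
        lines.append(
            f"{c['families_total']} families scored; "
            f"{c['core_families']} conserved in >= {c['min_networks']} networks"
        )
    if "consensus" in stages:
        c = stages["consensus"]
        lines.append(
            f"{c['families']} consensus families, {c['relationships']} relationships "
            f"({c['self_loops']} self-loops)"
        )
    if "phylo" in stages:
        strata = stages["phylo"]["strata"]
        lines.append(
            "first appearance: "
            + ", ".join(f"{k}={v}" for k, v in strata.items())
        )
    if "relevance" in stages:
        lines.append(f"relevance tally over {stages['relevance']['genes_counted']} genes")
    if not lines:
        lines.append("0 consensus families")
    return "\n".join(lines)
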