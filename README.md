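# coexnet

Comparative co-expression network analysis across species. Given per-species
co-expression networks (undirected gene edge lists), a gene→family mapping,
functional-annotation bins, and a clade presence/absence table, the pipeline:

1. **extracts** the bait-centered neighborhood of each network (all genes
   within *k* hops of any bait gene, induced subgraph);
2. **scores conservation** of gene families — the number of networks a family
   occurs in — and filters the conserved core;
3. **builds a consensus network** at the family level, keeping only nodes and
   relationships supported in enough species (self-loops mark intra-family
   co-expression);
4. **overlays phylostratigraphy** — each family's first-appearance clade from
   an ordered lineage table;
5. **tallies annotation composition** (target / unknown / other bins) per
   conservation class.

A synthetic-data generator plants a conserved core across species so the whole
pipeline is testable without any external downloads.

## Test

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria: brute-force oracle
equivalence for every stage, planted-core recovery, and determinism checks.

## CLI

Each stage is a subcommand; `run` chains them from one YAML config.

```sh
# generate a synthetic 4-species bundle with a planted core
coexnet simulate --seed 1 --out sim/

# single stages
coexnet extract --network sim/network_sp1.tsv --baits sim/baits/baits_sp1.txt \
    --steps 2 --out sub_sp1.tsv
coexnet conserve --networks a.tsv --networks b.tsv --families fam.tsv --out core/
coexnet consensus --networks a.tsv --networks b.tsv --families fam.tsv \
    --min-node 3 --min-edge 3 --out consensus.graphml
coexnet phylo --consensus consensus.graphml --lineage lineage.tsv \
    --out annotated.graphml --summary strata.tsv
coexnet relevance --networks a.tsv --networks b.tsv --families fam.tsv \
    --annotation mapman.tsv --target-bins 10 --unknown-bins 35 --out relevance.tsv

# full pipeline
coexnet run --config pipeline.yaml
```

Example `pipeline.yaml` (paths resolve relative to the config file):

```yaml
networks:
  - {path: network_sp1.tsv, species_id: sp1, baits_file: baits/baits_sp1.txt}
  - {path: network_sp2.tsv, species_id: sp2, baits: [sp2_CORE0001_g0]}
family_map: families.tsv
annotation: annotation.tsv   # optional
lineage: lineage.tsv         # optional
output_dir: run/
steps: 2
min_node_support: 3
min_edge_support: 3
```

Outputs land in `output_dir`: per-network neighborhood TSVs and labeled
GraphML, a conservation-profile TSV (family, count, member genes per network),
class-distribution TSV, conserved-core GraphML per network, the consensus
GraphML with node/edge supports and strata, relevance TSV, strata summary, and
`summary.json` with per-stage counts.

## File formats

* **Edge list** — TSV `gene_a<TAB>gene_b`; `#` lines skipped; one-column lines
  declare isolated nodes; a third column (e.g. a weight) is ignored.
* **Family map** — TSV `gene<TAB>family`; one family per gene.
* **Annotation** — TSV `gene<TAB>bin`; multiple rows per gene; hierarchical
  bins (`10.2.1`) match by their top-level code.
* **Lineage** — TSV header `family<TAB>clade1<TAB>...` with clades ordered
  oldest first; cells are 0/1.

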