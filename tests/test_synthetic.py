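import filecmp
import random

import pytest

from coexnet.conservation import conservation_profile
from coexnet.io import UNASSIGNED
from coexnet.neighborhood import BaitSet, extract_neighborhood
from coexnet.phylostrat import first_appearance
from coexnet.synthetic import SyntheticBundle, SyntheticSpec, generate, write_bundle

SMALL = dict(
    n_species=3,
    n_core_families=6,
    genes_per_family=2,
    n_noise_genes_per_species=30,
    core_edge_prob=0.4,
    noise_edge_prob=0.02,
)


def recovered_core(bundle, steps=2):
    nbrs = []
    for net in bundle.networks:
        baits = frozenset(bundle.ground_truth["bait_genes"][net.species_id])
        nbrs.append(extract_neighborhood(net, BaitSet(net.species_id, baits), steps).network)
    profile = conservation_profile(nbrs, bundle.family_map)
    s = len(bundle.networks)
    return {f for f, c in profile.counts.items() if c == s}


class TestSpecValidation:
    def test_zero_core_families_rejected(self):
        with pytest.raises(ValueError, match="core family"):
            SyntheticSpec(n_core_families=0)

    def test_single_species_rejected(self):
        with pytest.raises(ValueError):
            SyntheticSpec(n_species=1)

    def test_bad_probability(self):
        with pytest.raises(ValueError):
            SyntheticSpec(core_edge_prob=0.0)
        with pytest.raises(ValueError):
            SyntheticSpec(noise_edge_prob=1.0)

    def test_weights_must_align_with_clades(self):
        with pytest.raises(ValueError):
            SyntheticSpec(clades=("a", "b"), core_stratum_weights=(1.0,))

    def test_unknown_bait_family_rejected(self):
        with pytest.raises(ValueError, match="bait_family"):
            SyntheticSpec(bait_family="NOPE")


def test_zero_noise_every_core_family_in_all_networks():
    spec = SyntheticSpec(**{**SMALL, "noise_edge_prob": 0.0, "core_edge_prob": 1.0}, seed=7)
    bundle = generate(spec)
    profile = conservation_profile(bundle.networks, bundle.family_map)
    for fam in bundle.ground_truth["core_families"]:
        assert profile.counts[fam] == spec.n_species


def test_zero_noise_pipeline_recovers_exactly_the_core():
    spec = SyntheticSpec(**{**SMALL, "noise_edge_prob": 0.0}, seed=11)
    bundle = generate(spec)
    assert recovered_core(bundle) == set(bundle.ground_truth["core_families"])


def test_same_seed_byte_identical(tmp_path):
    spec = SyntheticSpec(**SMALL, seed=42)
    write_bundle(generate(spec), tmp_path / "a")
    write_bundle(generate(spec), tmp_path / "b")
    a, b = tmp_path / "a", tmp_path / "b"
    names = sorted(p.name for p in a.iterdir() if p.is_file())
    assert names == sorted(p.name for p in b.iterdir() if p.is_file())
    match, mismatch, errors = filecmp.cmpfiles(a, b, names, shallow=False)
    assert not mismatch and not errors


def test_different_seeds_differ():
    a = generate(SyntheticSpec(**SMALL, seed=1))
    b = generate(SyntheticSpec(**SMALL, seed=2))
    assert {n.species_id: n.edges for n in a.networks} != {
        n.species_id: n.edges for n in b.networks
    }


def test_monte_carlo_core_conservation_over_seeds():
    hits = total = 0
    for seed in range(20):
        spec = SyntheticSpec(
            n_species=4,
            n_core_families=20,
            genes_per_family=2,
            n_noise_genes_per_species=200,
            noise_edge_prob=0.01,
            seed=seed,
        )
        bundle = generate(spec)
        profile = conservation_profile(bundle.networks, bundle.family_map)
        for fam in bundle.ground_truth["core_families"]:
            total += 1
            if profile.counts.get(fam) == 4:
                hits += 1
    assert hits / total >= 0.95


def test_noise_families_never_co_occur():
    bundle = generate(SyntheticSpec(**SMALL, seed=3))
    profile = conservation_profile(bundle.networks, bundle.family_map)
    core = set(bundle.ground_truth["core_families"])
    for fam, count in profile.counts.items():
        if fam not in core:
            assert count == 1


def test_outputs_satisfy_type_invariants():
    bundle = generate(SyntheticSpec(**SMALL, seed=5))
    for net in bundle.networks:
        assert all(a != b for a, b in net.edges)
    assert UNASSIGNED not in set(bundle.family_map.entries.values())
    for fam, vec in bundle.lineage.presence.items():
        assert len(vec) == len(bundle.lineage.clades)
    # every gene in every network is mapped and annotated
    for net in bundle.networks:
        for gene in net.nodes:
            assert gene in bundle.family_map
            assert bundle.annotation.bins_of(gene)


def test_ground_truth_strata_match_first_appearance():
    bundle = generate(SyntheticSpec(**SMALL, seed=9))
    strata = first_appearance(bundle.lineage)
    assert strata == bundle.ground_truth["strata"]


def test_core_lineage_presence_is_contiguous_from_origin():
    bundle = generate(SyntheticSpec(**SMALL, seed=13))
    for fam in bundle.ground_truth["core_families"]:
        vec = bundle.lineage.presence[fam]
        first = vec.index(True)
        assert all(vec[first:])


def test_repairs_guarantee_two_step_reachability():
    # sparse core: repairs must kick in and still yield full recovery
    spec = SyntheticSpec(
        n_species=3,
        n_core_families=15,
        genes_per_family=1,
        n_noise_genes_per_species=0,
        core_edge_prob=0.01,
        noise_edge_prob=0.0,
        seed=21,
    )
    bundle = generate(spec)
    assert bundle.repairs  # with p=0.01 the core cannot be connected by luck
    assert recovered_core(bundle) == set(bundle.ground_truth["core_families"])


def test_write_bundle_emits_readable_files(tmp_path):
    from coexnet.io import (
        read_annotation,
        read_edge_list,
        read_family_map,
        read_lineage_table,
    )

    bundle = generate(SyntheticSpec(**SMALL, seed=17))
    paths = write_bundle(bundle, tmp_path)
    fam = read_family_map(paths["families"])
    assert dict(fam.entries) == dict(bundle.family_map.entries)
    ann = read_annotation(paths["annotation"])
    assert {g: set(b) for g, b in ann.entries.items()} == {
        g: set(b) for g, b in bundle.annotation.entries.items()
    }
    lineage = read_lineage_table(paths["lineage"])
    assert lineage.clades == bundle.lineage.clades
    for net in bundle.networks:
        back = read_edge_list(paths[f"network_{net.species_id}"], net.species_id)
        assert back.nodes == net.nodes
        assert back.edges == net.edges
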