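import random

import pytest

from coexnet.consensus import build_consensus, collapse_to_family_graph
from coexnet.conservation import conservation_profile
from coexnet.io import FamilyMap, GeneNetwork
from tests.conftest import random_family_map, random_network
from tests.oracles import collapse_family_edges, union_consensus


def make_instance(rng, n_nets=4):
    nets = [random_network(rng, f"sp{i}", max_nodes=30) for i in range(n_nets)]
    genes = sorted(set().union(*(net.nodes for net in nets)))
    fam = FamilyMap(random_family_map(rng, genes, n_families=6))
    return nets, fam


class TestCollapse:
    def test_intra_family_adjacency_gives_self_loop(self):
        net = GeneNetwork("sp0")
        net.add_edge("cesa1", "cesa2")
        fam = FamilyMap({"cesa1": "CESA", "cesa2": "CESA"})
        fnet = collapse_to_family_graph(net, fam)
        assert ("CESA", "CESA") in fnet.edges

    def test_no_self_loop_without_intra_family_edge(self):
        net = GeneNetwork("sp0")
        net.add_node("cesa1")
        net.add_node("cesa2")
        net.add_edge("cesa1", "other")
        fam = FamilyMap({"cesa1": "CESA", "cesa2": "CESA", "other": "OTH"})
        fnet = collapse_to_family_graph(net, fam)
        assert ("CESA", "CESA") not in fnet.edges
        assert ("CESA", "OTH") in fnet.edges

    def test_single_gene_no_edges(self):
        net = GeneNetwork("sp0")
        net.add_node("g1")
        fnet = collapse_to_family_graph(net, FamilyMap({"g1": "F1"}))
        assert fnet.nodes == {"F1"}
        assert fnet.edges == set()

    def test_unassigned_genes_excluded(self):
        net = GeneNetwork("sp0")
        net.add_edge("g1", "mystery")
        fnet = collapse_to_family_graph(net, FamilyMap({"g1": "F1"}))
        assert fnet.nodes == {"F1"}
        assert fnet.edges == set()

    def test_matches_exhaustive_pair_oracle(self, rng):
        for _ in range(25):
            net = random_network(rng, "sp0", max_nodes=30)
            fam_map = random_family_map(rng, sorted(net.nodes), n_families=5)
            fnet = collapse_to_family_graph(net, FamilyMap(fam_map))
            exp_nodes, exp_edges = collapse_family_edges(net.nodes, net.edges, fam_map)
            assert fnet.nodes == exp_nodes
            # oracle only sees inter-gene pairs a<b, so covers self-loops too
            assert fnet.edges == exp_edges


class TestBuildConsensus:
    def test_edge_support_threshold(self):
        nets, fams = [], {}
        for i in range(4):
            net = GeneNetwork(f"sp{i}")
            net.add_node(f"a{i}")
            net.add_node(f"b{i}")
            if i < 3:  # edge in 3 of 4 networks
                net.add_edge(f"a{i}", f"b{i}")
            nets.append(net)
            fams[f"a{i}"] = "FA"
            fams[f"b{i}"] = "FB"
        fam = FamilyMap(fams)
        profile = conservation_profile(nets, fam)
        family_nets = [collapse_to_family_graph(n, fam) for n in nets]
        kept = build_consensus(family_nets, profile, 3, 3)
        assert kept.edge_support("FA", "FB") == 3
        dropped = build_consensus(family_nets, profile, 3, 4)
        assert ("FA", "FB") not in dropped.edges

    def test_identical_networks_idempotent(self, rng):
        base = random_network(rng, "sp0", max_nodes=20)
        fam = FamilyMap(random_family_map(rng, sorted(base.nodes), unmapped_frac=0.0))
        nets = [GeneNetwork(f"sp{i}", base.graph.copy()) for i in range(4)]
        profile = conservation_profile(nets, fam)
        family_nets = [collapse_to_family_graph(n, fam) for n in nets]
        cons = build_consensus(family_nets, profile, 4, 4)
        assert cons.nodes == family_nets[0].nodes
        assert cons.edges == family_nets[0].edges
        assert all(cons.node_support(f) == 4 for f in cons.nodes)
        assert all(cons.edge_support(a, b) == 4 for a, b in cons.edges)

    def test_self_loop_support_counts_networks(self):
        nets, fams = [], {}
        for i in range(4):
            net = GeneNetwork(f"sp{i}")
            net.add_edge(f"c1_{i}", f"c2_{i}")
            nets.append(net)
            fams[f"c1_{i}"] = "CESA"
            fams[f"c2_{i}"] = "CESA"
        fam = FamilyMap(fams)
        profile = conservation_profile(nets, fam)
        cons = build_consensus(
            [collapse_to_family_graph(n, fam) for n in nets], profile, 4, 4
        )
        assert cons.edge_support("CESA", "CESA") == 4

    def test_thresholds_at_one_equal_brute_force_union(self, rng):
        for _ in range(20):
            nets, fam = make_instance(rng)
            profile = conservation_profile(nets, fam)
            family_nets = [collapse_to_family_graph(n, fam) for n in nets]
            cons = build_consensus(family_nets, profile, 1, 1)
            expected_occ = union_consensus([f.edges for f in family_nets])
            assert cons.edges == set(expected_occ)
            for a, b in cons.edges:
                assert cons.edge_support(a, b) == expected_occ[(a, b)]
            assert cons.nodes == set(profile.counts)

    def test_monotone_in_both_thresholds(self, rng):
        nets, fam = make_instance(rng)
        profile = conservation_profile(nets, fam)
        family_nets = [collapse_to_family_graph(n, fam) for n in nets]
        s = len(nets)
        results = {
            (n, e): build_consensus(family_nets, profile, n, e)
            for n in range(1, s + 1)
            for e in range(1, s + 1)
        }
        for (n, e), cons in results.items():
            for (n2, e2), stricter in results.items():
                if n2 >= n and e2 >= e:
                    assert stricter.nodes <= cons.nodes
                    assert stricter.edges <= cons.edges

    def test_order_invariance(self, rng):
        nets, fam = make_instance(rng)
        profile = conservation_profile(nets, fam)
        family_nets = [collapse_to_family_graph(n, fam) for n in nets]
        a = build_consensus(family_nets, profile, 2, 2)
        b = build_consensus(list(reversed(family_nets)), profile, 2, 2)
        assert a.nodes == b.nodes and a.edges == b.edges

    def test_threshold_out_of_range(self, rng):
        nets, fam = make_instance(rng)
        profile = conservation_profile(nets, fam)
        family_nets = [collapse_to_family_graph(n, fam) for n in nets]
        with pytest.raises(ValueError):
            build_consensus(family_nets, profile, 0, 1)
        with pytest.raises(ValueError):
            build_consensus(family_nets, profile, 1, len(nets) + 1)
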