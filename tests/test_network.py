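"""Parsimony network construction, ambiguity resolution, and contrasts."""

import itertools

import networkx as nx
import numpy as np
import pytest

from conftest import make_haplotypes
from oracles import min_connection_weight
from mtscan import (
    SimConfig,
    build_network,
    enumerate_contrasts,
    hamming,
    resolve_ambiguities,
    score_ancestry,
    simulate_dataset,
)
from mtscan.network import AmbiguityLoop, HaplotypeNetwork


class TestHamming:
    def test_basic(self):
        assert hamming([0, 1], [0, 1]) == 0
        assert hamming([0, 0], [1, 1]) == 2

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            hamming([0], [0, 1])

    def test_matches_bitcount_oracle(self, rng):
        for _ in range(50):
            a = rng.integers(0, 2, size=20)
            b = rng.integers(0, 2, size=20)
            expected = bin(
                int("".join(map(str, a)), 2) ^ int("".join(map(str, b)), 2)
            ).count("1")
            assert hamming(a, b) == expected


class TestBuildNetwork:
    def test_three_haplotype_path(self):
        haps = make_haplotypes(["00", "01", "11"])
        net = build_network(haps)
        G = net.graph
        assert net.n_nodes == 3 and net.n_edges == 2
        edges = {frozenset((u, v)): d["site"] for u, v, d in G.edges(data=True)}
        assert edges[frozenset(("H001", "H002"))] == 1  # 00-01 differs at site 2
        assert edges[frozenset(("H002", "H003"))] == 0  # 01-11 differs at site 1
        assert not net.ambiguity_loops

    def test_two_step_connection_inserts_intermediate(self):
        haps = make_haplotypes(["00", "11"])
        net = build_network(haps)
        assert net.n_nodes == 3 and net.n_edges == 2
        inferred = [n for n, d in net.graph.nodes(data=True) if not d["observed"]]
        assert len(inferred) == 1
        loops = [l for l in net.ambiguity_loops if l.kind == "path_order"]
        assert len(loops) == 1
        assert loops[0].n_alternative_orders == 1  # the other site order

    def test_single_haplotype(self):
        net = build_network(make_haplotypes(["0101"]))
        assert net.n_nodes == 1 and net.n_edges == 0

    def test_every_edge_changes_one_site(self, small_sim):
        net = build_network(small_sim.haplotypes, variants=small_sim.matrix.variants)
        for u, v, d in net.graph.edges(data=True):
            va = np.array(net.graph.nodes[u]["alleles"])
            vb = np.array(net.graph.nodes[v]["alleles"])
            diff = np.flatnonzero(va != vb)
            assert len(diff) == 1 and diff[0] == d["site"]

    def test_tree_path_length_equals_hamming(self, small_sim):
        net = build_network(small_sim.haplotypes, variants=small_sim.matrix.variants)
        G = net.graph
        nodes = list(G.nodes)
        lengths = dict(nx.all_pairs_shortest_path_length(G))
        for a, b in itertools.combinations(nodes, 2):
            d = hamming(G.nodes[a]["alleles"], G.nodes[b]["alleles"])
            assert lengths[a][b] == d

    def test_edge_count_matches_brute_force_small(self, rng):
        for _ in range(25):
            n = int(rng.integers(2, 7))
            vecs = set()
            while len(vecs) < n:
                vecs.add(tuple(int(x) for x in rng.integers(0, 2, size=5)))
            haps = make_haplotypes(["".join(map(str, v)) for v in sorted(vecs)])
            net = build_network(haps)
            D = np.array(
                [[hamming(a.alleles, b.alleles) for b in haps] for a in haps]
            )
            assert net.tree_edge_count == min_connection_weight(D)

    def test_disconnected_at_limit_flagged(self):
        haps = make_haplotypes(["0000", "1111"])
        net = build_network(haps, max_connection_steps=2)
        assert not net.connected


class TestScoreAncestry:
    def test_star_center_is_root(self):
        haps = make_haplotypes(
            ["000", "100", "010", "001"], counts=[10, 1, 1, 1]
        )
        net = build_network(haps)
        score_ancestry(net)
        assert net.root_id == "H001"

    def test_path_middle_is_root_for_equal_counts(self):
        haps = make_haplotypes(["00", "01", "11"], counts=[1, 1, 1])
        net = build_network(haps)
        scores = score_ancestry(net)
        # closeness on a 3-path: middle 1.0, tips 2/3 (normalized)
        assert net.root_id == "H002"
        assert scores["H002"] > scores["H001"] == scores["H003"]

    def test_two_node_tie_breaks_lexicographically(self):
        haps = make_haplotypes(["0", "1"], counts=[3, 3])
        net = build_network(haps)
        score_ancestry(net)
        assert net.root_id == "H001"  # smaller allele vector wins


def _loop_network(counts):
    """4-cycle A-B-C-D-A with a recorded loop: child C, parents B and D."""
    G = nx.Graph()
    vecs = {"A": (0, 0), "B": (0, 1), "C": (1, 1), "D": (1, 0)}
    for i, (n, v) in enumerate(vecs.items()):
        G.add_node(n, alleles=v, observed=True, count=counts[i])
    G.add_edge("A", "B", site=1)
    G.add_edge("B", "C", site=0)
    G.add_edge("C", "D", site=1)
    G.add_edge("D", "A", site=0)
    loop = AmbiguityLoop(
        loop_id="L001",
        kind="connection",
        child="C",
        candidate_edges=[("C", "B"), ("C", "D")],
    )
    return HaplotypeNetwork(graph=G, ambiguity_loops=[loop])


class TestResolveAmbiguities:
    def test_age_criterion_picks_higher_score(self):
        net = _loop_network(counts=[5, 8, 1, 1])  # B much more frequent
        resolve_ambiguities(net)
        loop = net.ambiguity_loops[0]
        assert loop.resolution == "resolved_by_age"
        assert loop.chosen_edge == ("C", "B")
        assert not net.graph.has_edge("C", "D")
        assert net.n_nodes == 4 and net.n_edges == 3

    def test_frequency_criterion_on_score_tie(self):
        net = _loop_network(counts=[1, 5, 1, 1])
        # force a score tie so the frequency rule must decide
        net.ancestry_scores = {"A": 0.1, "B": 0.5, "C": 0.1, "D": 0.5}
        net.root_id = "B"
        resolve_ambiguities(net)
        loop = net.ambiguity_loops[0]
        assert loop.resolution == "resolved_by_frequency"
        assert loop.chosen_edge == ("C", "B")

    def test_double_tie_stays_unresolved(self):
        net = _loop_network(counts=[1, 2, 1, 2])
        net.ancestry_scores = {n: 0.5 for n in "ABCD"}
        net.root_id = "A"
        n_edges = net.n_edges
        resolve_ambiguities(net)
        assert net.ambiguity_loops[0].resolution == "unresolved"
        assert net.n_edges == n_edges  # loop retained

    def test_resolution_reduces_edges_by_loops_resolved(self):
        cfg = SimConfig(
            n_individuals=60, n_haplotypes=12, n_sites=30, n_homoplasy=1, seed=5
        )
        data = simulate_dataset(cfg)
        net = build_network(data.haplotypes, variants=data.matrix.variants)
        n_nodes, n_edges = net.n_nodes, net.n_edges
        score_ancestry(net)
        resolve_ambiguities(net)
        resolved = sum(
            1
            for l in net.ambiguity_loops
            if l.kind == "connection" and l.resolution != "unresolved"
        )
        assert net.n_nodes == n_nodes
        assert net.n_edges == n_edges - resolved


class TestEnumerateContrasts:
    def test_path_through_inferred_node_merges_cuts(self):
        haps = make_haplotypes(["00", "11"], counts=[3, 2])
        net = build_network(haps)
        score_ancestry(net)
        resolve_ambiguities(net)
        contrasts = enumerate_contrasts(net, haps)
        assert len(contrasts) == 1
        c = contrasts[0]
        assert len(c.branch_ids) == 2  # both edges induce the same split
        assert {c.side_a, c.side_b} == {frozenset({"H001"}), frozenset({"H002"})}

    def test_star_yields_tip_vs_rest(self):
        haps = make_haplotypes(["000", "100", "010", "001"], counts=[5, 1, 1, 1])
        net = build_network(haps)
        score_ancestry(net)
        resolve_ambiguities(net)
        contrasts = enumerate_contrasts(net, haps)
        assert len(contrasts) == 3
        for c in contrasts:
            assert len(c.side_a) == 1 and len(c.side_b) == 3

    def test_contrast_count_bounded_by_edges(self, small_sim):
        net = build_network(small_sim.haplotypes, variants=small_sim.matrix.variants)
        score_ancestry(net)
        resolve_ambiguities(net)
        contrasts = enumerate_contrasts(net, small_sim.haplotypes)
        assert len(contrasts) <= net.n_edges

    def test_bipartitions_are_proper(self, small_sim):
        net = build_network(small_sim.haplotypes, variants=small_sim.matrix.variants)
        score_ancestry(net)
        resolve_ambiguities(net)
        contrasts = enumerate_contrasts(net, small_sim.haplotypes)
        all_haps = {h.haplotype_id for h in small_sim.haplotypes}
        all_inds = {i for h in small_sim.haplotypes for i in h.members}
        for c in contrasts:
            assert c.side_a and c.side_b
            assert not (c.side_a & c.side_b)
            assert c.side_a | c.side_b == all_haps
            assert not (c.individuals_a & c.individuals_b)
            assert c.individuals_a | c.individuals_b == all_inds
            assert len(c.individuals_a) <= len(c.individuals_b)

    def test_unresolved_loop_enumerates_both_resolutions(self):
        net = _loop_network(counts=[1, 2, 1, 2])
        net.ancestry_scores = {n: 0.5 for n in "ABCD"}
        net.root_id = "A"
        resolve_ambiguities(net)
        haps = make_haplotypes(["00", "01", "11", "10"], counts=[1, 2, 1, 2])
        # align hand-built node names with haplotype ids
        mapping = {"A": "H001", "B": "H002", "C": "H003", "D": "H004"}
        nx.relabel_nodes(net.graph, mapping, copy=False)
        for loop in net.ambiguity_loops:
            loop.child = mapping[loop.child]
            loop.candidate_edges = [
                (mapping[u], mapping[v]) for u, v in loop.candidate_edges
            ]
        contrasts = enumerate_contrasts(net, haps)
        resolutions = {c.resolution_id for c in contrasts}
        assert resolutions == {"R0", "R1"}
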