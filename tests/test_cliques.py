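"""Insertion graph, maximal-clique enumeration, compartments."""

import itertools

import networkx as nx
import numpy as np
import pytest

from pante.cliques import (InsertionClique, build_insertion_graph,
                           classify_compartments, compartment_boundaries,
                           compartment_of_size, enumerate_maximal_cliques,
                           flag_relocations)
from pante.config import PipelineConfig
from pante.io_formats import TECopy
from pante.matching import MatchEdge


def edge(a_acc, a_id, b_acc, b_id):
    return MatchEdge(a_acc, a_id, b_acc, b_id, 10.0, 1, 1, 1, 1)


def node(i):
    return (f"acc{i}", f"c{i}")


class TestBuildGraph:
    def test_triangle(self):
        graph = build_insertion_graph([
            edge("a1", "x", "a2", "y"), edge("a2", "y", "a3", "z"),
            edge("a1", "x", "a3", "z")])
        assert graph.number_of_nodes() == 3 and graph.number_of_edges() == 3

    def test_empty_edges_keep_declared_nodes(self):
        graph = build_insertion_graph([], nodes=[node(1), node(2)])
        assert graph.number_of_nodes() == 2 and graph.number_of_edges() == 0

    def test_intra_accession_edge_rejected(self):
        with pytest.raises(ValueError, match="different accessions"):
            edge("a1", "x", "a1", "y")  # rejected at construction
        bad = MatchEdge.__new__(MatchEdge)  # and again by the graph builder
        bad.accession_a = bad.accession_b = "a1"
        bad.copy_a_id, bad.copy_b_id = "x", "y"
        with pytest.raises(ValueError, match="one accession"):
            build_insertion_graph([bad])

    def test_duplicate_edges_collapse(self):
        graph = build_insertion_graph([edge("a1", "x", "a2", "y")] * 3)
        assert graph.number_of_edges() == 1


class TestEnumerate:
    def test_triangle_is_one_clique(self):
        graph = build_insertion_graph([
            edge("a1", "x", "a2", "y"), edge("a2", "y", "a3", "z"),
            edge("a1", "x", "a3", "z")])
        cliques = enumerate_maximal_cliques(graph)
        assert len(cliques) == 1 and cliques[0].size == 3

    def test_path_gives_two_cliques(self):
        graph = build_insertion_graph([
            edge("a1", "x", "a2", "y"), edge("a2", "y", "a3", "z")])
        cliques = enumerate_maximal_cliques(graph)
        assert sorted(c.size for c in cliques) == [2, 2]

    def test_isolated_nodes_become_singletons(self):
        graph = build_insertion_graph([edge("a1", "x", "a2", "y")],
                                      nodes=[node(7)])
        cliques = enumerate_maximal_cliques(graph)
        sizes = sorted(c.size for c in cliques)
        assert sizes == [1, 2]
        singles = [c for c in cliques if c.size == 1]
        assert singles[0].clique_id.startswith("singleton")

    def test_matches_bruteforce_on_random_graphs(self):
        """Spot-check against exhaustive subset enumeration (the full
        100-graph comparison runs in the acceptance suite)."""
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = int(rng.integers(2, 11))
            graph = nx.fast_gnp_random_graph(n, 0.4, seed=int(rng.integers(2**31)))
            graph = nx.relabel_nodes(graph, {i: node(i) for i in range(n)})
            ours = {frozenset(c.members) for c in enumerate_maximal_cliques(graph)}
            assert ours == brute_force_cliques(graph)


def brute_force_cliques(graph):
    nodes = list(graph.nodes)
    complete = []
    for r in range(1, len(nodes) + 1):
        for subset in itertools.combinations(nodes, r):
            if all(graph.has_edge(u, v) for u, v in itertools.combinations(subset, 2)):
                complete.append(frozenset(subset))
    return {c for c in complete
            if not any(c < other for other in complete)}


class TestCompartments:
    def test_panel_of_42_reproduces_printed_ranges(self, config):
        # cloud 2-7, shell 8-38, soft-core 39-41, core 42
        labels = {s: compartment_of_size(s, 42, config) for s in range(1, 43)}
        assert labels[1] == "singleton"
        assert all(labels[s] == "cloud" for s in range(2, 8))
        assert all(labels[s] == "shell" for s in range(8, 39))
        assert all(labels[s] == "soft_core" for s in range(39, 42))
        assert labels[42] == "core"

    def test_boundaries_are_floors_of_fractions(self, config):
        assert compartment_boundaries(42, config) == (8, 39)
        assert compartment_boundaries(10, config) == (2, 9)

    def test_small_panel_rejected(self, config):
        with pytest.raises(ValueError):
            compartment_of_size(1, 1, config)

    def test_classify_labels_all_cliques(self, small_result, config):
        n = len(small_result.accessions)
        for cl in small_result.cliques:
            assert cl.compartment == compartment_of_size(cl.size, n, config)

    def test_no_clique_with_two_copies_of_one_accession(self):
        with pytest.raises(ValueError, match="one accession"):
            InsertionClique("x", frozenset([("a1", "c1"), ("a1", "c2")]))


class TestRelocations:
    def copies(self, chroms):
        return {(f"acc{i}", f"c{i}"): TECopy(f"c{i}", f"acc{i}", chrom, 0, 10, "+",
                                             "x", 0, 1, 99.0)
                for i, chrom in enumerate(chroms)}

    def test_same_chromosome_not_flagged(self):
        copies = self.copies(["chr1", "chr1", "chr1"])
        cl = InsertionClique("c", frozenset(copies))
        assert not flag_relocations([cl], copies)[0].relocation_flag

    def test_two_chromosomes_flagged(self):
        copies = self.copies(["chr1", "chr3"])
        cl = InsertionClique("c", frozenset(copies))
        assert flag_relocations([cl], copies)[0].relocation_flag

    def test_singleton_never_flagged(self):
        copies = self.copies(["chr1"])
        cl = InsertionClique("c", frozenset(copies))
        assert not flag_relocations([cl], copies)[0].relocation_flag
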