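"""Fragment merging, reciprocal best hits, and the flank-overlap filter."""

import itertools

import numpy as np
import pytest

from pante.config import PipelineConfig
from pante.copy_extraction import FlankedCopy
from pante.io_formats import AlignmentFragment, TECopy
from pante.matching import (flank_overlap_filter, match_genome_pair, merge_collinear,
                            reciprocal_best_hits, select_best_hits, MatchEdge)
from pante import simulate_pangenome


def frag(q0, q1, t0, t1, score, qid="q1", tid="t1", orientation="+"):
    return AlignmentFragment(qid, tid, q0, q1, t0, t1, orientation, score, 99.0)


class TestMergeCollinear:
    def test_merges_nearby_collinear_fragments(self):
        fragments = [frag(0, 400, 0, 400, 100), frag(450, 900, 460, 910, 120)]
        merged = merge_collinear(fragments, merge_max_gap=500)
        assert len(merged) == 1
        m = merged[0]
        assert (m.q_start, m.q_end, m.t_start, m.t_end) == (0, 900, 0, 910)
        assert m.score == 220

    def test_opposite_orientation_not_merged(self):
        fragments = [frag(0, 400, 0, 400, 100),
                     frag(450, 900, 460, 910, 120, orientation="-")]
        assert len(merge_collinear(fragments, 500)) == 2

    def test_query_overlap_not_merged(self):
        fragments = [frag(0, 400, 0, 400, 100), frag(300, 700, 420, 820, 120)]
        assert len(merge_collinear(fragments, 500)) == 2

    def test_gap_above_limit_not_merged(self):
        fragments = [frag(0, 400, 0, 400, 100), frag(950, 1300, 960, 1310, 120)]
        assert len(merge_collinear(fragments, 500)) == 2


def copy_at(cid, start, chrom="chr1", acc="accB"):
    return TECopy(cid, acc, chrom, start, start + 100, "+", "x", 0, 1, 99.0)


class TestSelectBestHits:
    LOOKUP = {"t1": copy_at("t1", 1000), "t2": copy_at("t2", 500),
              "t3": copy_at("t3", 500, chrom="chr0")}

    def test_maximal_score_wins(self):
        matches = [frag(0, 100, 0, 100, 100, tid="t1"),
                   frag(0, 100, 0, 100, 80, tid="t2")]
        best = select_best_hits(matches, self.LOOKUP)
        assert best["q1"].target_copy_id == "t1"

    def test_tie_broken_by_target_position(self):
        matches = [frag(0, 100, 0, 100, 100, tid="t1"),
                   frag(0, 100, 0, 100, 100, tid="t2"),
                   frag(0, 100, 0, 100, 100, tid="t3")]
        # chr0 sorts before chr1; among chr1 targets, smaller start wins
        best = select_best_hits(matches, self.LOOKUP)
        assert best["q1"].target_copy_id == "t3"

    def test_query_without_match_absent(self):
        assert "q9" not in select_best_hits([frag(0, 9, 0, 9, 5, tid="t1")], self.LOOKUP)


def flanked(cid, acc, lf=0, rf=0, length=100, start=1000):
    copy = TECopy(cid, acc, "chr1", start, start + length, "+", "x", 0, 1, 99.0)
    return FlankedCopy(copy, start - lf, start + length + rf, lf, rf,
                       sequence="A" * (lf + length + rf))


class TestReciprocalBestHits:
    def rbh(self, best_ab, best_ba):
        fa = {f.query_copy_id: flanked(f.query_copy_id, "A") for f in best_ab.values()}
        fb = {f.target_copy_id: flanked(f.target_copy_id, "B") for f in best_ab.values()}
        for f in best_ba.values():
            fa.setdefault(f.query_copy_id, flanked(f.query_copy_id, "A"))
            fb.setdefault(f.target_copy_id, flanked(f.target_copy_id, "B"))
        return reciprocal_best_hits(best_ab, best_ba, fa, fb, "A", "B")

    def test_mutual_best_kept(self):
        f = frag(0, 100, 0, 100, 50, qid="a1", tid="b1")
        assert len(self.rbh({"a1": f}, {"b1": f})) == 1

    def test_non_mutual_dropped(self):
        fab = frag(0, 100, 0, 100, 50, qid="a1", tid="b1")
        fba = frag(0, 100, 0, 100, 60, qid="a2", tid="b1")  # b1 prefers a2
        assert self.rbh({"a1": fab}, {"b1": fba}) == []

    def test_partial_matching_over_random_best_maps(self):
        """RBH edges form a one-to-one partial matching for any pair of
        best-hit maps over <= 5 copies (exhaustive over random score draws)."""
        rng = np.random.default_rng(42)
        for _ in range(200):
            n_a, n_b = rng.integers(1, 6), rng.integers(1, 6)
            scores = rng.integers(1, 5, size=(n_a, n_b))  # many ties
            matches = [frag(0, 100, 0, 100, int(scores[i, j]),
                            qid=f"a{i}", tid=f"b{j}")
                       for i in range(n_a) for j in range(n_b)]
            lookup_b = {f"b{j}": copy_at(f"b{j}", j * 100) for j in range(n_b)}
            lookup_a = {f"a{i}": copy_at(f"a{i}", i * 100, acc="accA") for i in range(n_a)}
            best_ab = select_best_hits(matches, lookup_b, "query")
            best_ba = select_best_hits(matches, lookup_a, "target")
            edges = self.rbh(best_ab, best_ba)
            assert len({e.copy_a_id for e in edges}) == len(edges)
            assert len({e.copy_b_id for e in edges}) == len(edges)


class TestFlankOverlapFilter:
    def edge(self, covs):
        return MatchEdge("A", "a1", "B", "b1", 100.0, *covs)

    def make_edge_from_span(self, span, lf=500, rf=500, length=1000):
        fc = flanked("a1", "A", lf, rf, length, start=1000)
        from pante.matching import _flank_coverage
        left, right = _flank_coverage(span[0], span[1], fc)
        return left, right

    def test_ninety_percent_coverage_passes(self):
        # 500 bp flanks around a 1000 bp copy: span [50, 1950) covers 450 bp
        # of each flank -> 0.9
        left, right = self.make_edge_from_span((50, 1950))
        assert (left, right) == (0.9, 0.9)
        assert flank_overlap_filter(self.edge([0.9, 0.9, 0.9, 0.9]), PipelineConfig())

    def test_seventy_percent_fails(self):
        left, _ = self.make_edge_from_span((150, 2000))
        assert left == pytest.approx(0.7)
        assert not flank_overlap_filter(self.edge([0.7, 1, 1, 1]), PipelineConfig())

    def test_exact_threshold_inclusive(self):
        assert flank_overlap_filter(self.edge([0.8, 0.8, 0.8, 0.8]), PipelineConfig())

    def test_combined_mode_pools_flank_bases(self):
        config = PipelineConfig(flank_overlap_mode="combined")
        fa = {"a1": flanked("a1", "A", 500, 500, 1000)}
        fb = {"b1": flanked("b1", "B", 500, 500, 1000)}
        # 0.7 on one flank, 0.9 on the rest: pooled = 0.85 >= 0.8
        edge = self.edge([0.7, 0.9, 0.9, 0.9])
        assert flank_overlap_filter(edge, config, fa, fb)
        assert not flank_overlap_filter(self.edge([0.7, 0.7, 0.7, 0.9]), config, fa, fb)


class TestGenomePair:
    def test_exact_genome_copies_give_full_coverage_edges(self, config):
        sim = simulate_pangenome(n_genomes=2, n_chromosomes=1, chrom_len=40_000,
                                 n_insertions=4, mutation_rate=0.0, seed=3,
                                 sharing_spec=[[0, 1]] * 4)
        from pante.pipeline import extract_stage
        flanked_by_acc = extract_stage(sim.assemblies, sim.copies, sim.library, config)
        a, b = sorted(flanked_by_acc)
        edges = match_genome_pair(flanked_by_acc[a], flanked_by_acc[b], a, b, config)
        assert len(edges) == 4
        for e in edges:
            assert e.flank_coverages == (1.0, 1.0, 1.0, 1.0)

    def test_order_invariance_of_edges(self, config):
        sim = simulate_pangenome(n_genomes=2, n_chromosomes=1, chrom_len=40_000,
                                 n_insertions=4, mutation_rate=0.02, seed=4,
                                 sharing_spec=[[0, 1]] * 4)
        from pante.pipeline import extract_stage
        fl = extract_stage(sim.assemblies, sim.copies, sim.library, config)
        a, b = sorted(fl)
        edges = match_genome_pair(fl[a], fl[b], a, b, config)
        edges_rev = match_genome_pair(list(reversed(fl[a])), list(reversed(fl[b])),
                                      a, b, config)
        key = lambda e: (e.copy_a_id, e.copy_b_id, e.total_score)
        assert sorted(map(key, edges)) == sorted(map(key, edges_rev))
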