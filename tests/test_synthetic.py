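"""Simulator determinism, end-to-end recovery on clean input, recovery
scoring, and nucleotide-level annotation accuracy."""

import numpy as np
import pytest

from pante import PipelineConfig, run_pipeline, simulate_pangenome
from pante.cliques import InsertionClique
from pante.io_formats import TECopy
from pante.synthetic import annotation_accuracy, score_recovery, PlantedTruth


class TestSimulator:
    def test_same_seed_is_byte_identical(self, tmp_path):
        a = simulate_pangenome(3, 1, 30_000, 3, 0.01, seed=5, out_dir=tmp_path / "a")
        b = simulate_pangenome(3, 1, 30_000, 3, 0.01, seed=5, out_dir=tmp_path / "b")
        for name in ("acc00.fa", "acc00.gff3", "truth.tsv", "library.fa"):
            assert (tmp_path / "a" / name).read_bytes() == (tmp_path / "b" / name).read_bytes()
        assert a.assemblies["acc01"].chromosomes == b.assemblies["acc01"].chromosomes

    def test_different_seeds_differ(self):
        a = simulate_pangenome(2, 1, 30_000, 2, 0.0, seed=1)
        b = simulate_pangenome(2, 1, 30_000, 2, 0.0, seed=2)
        assert a.assemblies["acc00"].chromosomes != b.assemblies["acc00"].chromosomes

    def test_annotation_matches_planted_sequence(self):
        sim = simulate_pangenome(2, 1, 30_000, 2, 0.0, seed=9, sharing_spec=[[0], [0, 1]])
        for acc, copies in sim.copies.items():
            for c in copies:
                seq = sim.assemblies[acc].chromosomes[c.chromosome][c.start:c.end]
                assert seq == sim.library_sequences[c.consensus_id]
                assert c.identity_pct == 100.0

    def test_mutations_reduce_identity(self):
        sim = simulate_pangenome(2, 1, 30_000, 4, 0.05, seed=9)
        identities = [c.identity_pct for copies in sim.copies.values() for c in copies]
        assert identities and all(80 < i < 100 for i in identities)

    def test_chromosome_too_small_rejected(self):
        with pytest.raises(ValueError, match="too small"):
            simulate_pangenome(2, 1, 10_000, 50, 0.0, seed=1)

    def test_insertions_well_separated(self):
        sim = simulate_pangenome(3, 2, 60_000, 10, 0.0, seed=2)
        for copies in sim.copies.values():
            by_chrom = {}
            for c in copies:
                by_chrom.setdefault(c.chromosome, []).append(c)
            for group in by_chrom.values():
                group.sort(key=lambda c: c.start)
                for prev, nxt in zip(group, group[1:]):
                    assert nxt.start - prev.end >= 2 * 500  # flanks never overlap


class TestEndToEndClean:
    def test_core_insertion_recovered_exactly(self, config):
        sim = simulate_pangenome(3, 1, 30_000, 1, 0.0, seed=5, sharing_spec=[[0, 1, 2]])
        res = run_pipeline(sim.assemblies, sim.copies, sim.library, config)
        shared = [c for c in res.cliques if c.size >= 2]
        assert len(shared) == 1 and shared[0].size == 3
        assert shared[0].compartment == "core"
        report = score_recovery(sim.truth, res.cliques, res.copies_by_key)
        assert (report["proportion"] == 1.0).all()
        assert (report["delta"].fillna(0) == 0).all()

    def test_private_insertion_is_singleton(self, config):
        sim = simulate_pangenome(3, 1, 30_000, 1, 0.0, seed=6, sharing_spec=[[0]])
        res = run_pipeline(sim.assemblies, sim.copies, sim.library, config)
        assert res.n_singletons == 1 and res.n_shared == 0

    def test_same_family_different_loci_stay_separate(self, config):
        """Two insertions of one family at different loci must not merge:
        the flank filter separates them."""
        lib = {"consX": "ACGT" * 500}
        sim = simulate_pangenome(2, 1, 40_000, 2, 0.0, seed=8,
                                 te_library=lib, sharing_spec=[[0, 1], [0, 1]])
        res = run_pipeline(sim.assemblies, sim.copies, sim.library, config)
        shared = [c for c in res.cliques if c.size >= 2]
        assert len(shared) == 2
        report = score_recovery(sim.truth, res.cliques, res.copies_by_key)
        assert (report["proportion"] == 1.0).all()


class TestScoreRecovery:
    def make(self, truth_accs, clique_accs):
        loci = {f"acc{i}": ("chr1", 100, 200) for i in truth_accs}
        truth = [PlantedTruth("ins0", "consA", tuple(sorted(loci)), loci, 0.0)]
        members = frozenset((f"acc{i}", f"c{i}") for i in clique_accs)
        copies = {(f"acc{i}", f"c{i}"): TECopy(f"c{i}", f"acc{i}", "chr1", 100, 200,
                                               "+", "consA", 0, 1, 99.0)
                  for i in clique_accs}
        return truth, [InsertionClique("cl1", members)], copies

    def test_perfect_recovery(self):
        truth, cliques, copies = self.make([0, 1, 2], [0, 1, 2])
        row = score_recovery(truth, cliques, copies).iloc[0]
        assert row.proportion == 1.0 and row.delta == 0

    def test_missing_carrier(self):
        truth, cliques, copies = self.make([0, 1, 2, 3], [0, 1, 2])
        row = score_recovery(truth, cliques, copies).iloc[0]
        assert row.proportion == 0.75 and row.delta == -1

    def test_no_overlapping_clique(self):
        truth, _, _ = self.make([0, 1], [])
        _, cliques, copies = self.make([0, 1], [0, 1])
        # shift clique copies to a different locus
        for c in copies.values():
            c.start, c.end = 5000, 5100
        row = score_recovery(truth, cliques, copies).iloc[0]
        assert row.proportion == 0.0 and np.isnan(row.delta)


class TestAnnotationAccuracy:
    def test_exact_prediction(self):
        rep = annotation_accuracy([(0, 100)], [(0, 100)], [(200, 400)])
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0 and rep.accuracy == 1.0

    def test_partial_sensitivity(self):
        rep = annotation_accuracy([(0, 80)], [(0, 100)], [])
        assert rep.sensitivity == pytest.approx(0.8)

    def test_false_positives_in_cds(self):
        rep = annotation_accuracy([(350, 450)], [(0, 100)], [(200, 400)])
        assert rep.fp == 50 and rep.tn == 150
        assert rep.specificity == pytest.approx(0.75)

    def test_fragmentation_invariance(self):
        whole = annotation_accuracy([(0, 100)], [(0, 100)], [(200, 300)])
        split = annotation_accuracy([(0, 40), (40, 100)],
                                    [(0, 60), (60, 100)], [(200, 250), (250, 300)])
        assert (whole.tp, whole.fp, whole.tn, whole.fn) == \
               (split.tp, split.fp, split.tn, split.fn)

    def test_gold_overlapping_cds_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            annotation_accuracy([(0, 10)], [(0, 100)], [(50, 150)])

    def test_chromosome_aware_intervals(self):
        rep = annotation_accuracy([("chr1", 0, 50), ("chr2", 0, 50)],
                                  [("chr1", 0, 100)], [("chr2", 0, 100)])
        assert rep.tp == 50 and rep.fp == 50 and rep.fn == 50 and rep.tn == 50
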