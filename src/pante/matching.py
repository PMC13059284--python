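"""Cross-genome matching of flank-extended copies.

For each pair of genomes, flank-extended copies are aligned copy-vs-copy
(built-in seed-and-extend aligner, or fragments from an external PAF),
nearby collinear fragments are merged, reciprocal best hits are selected,
and each candidate edge is validated by requiring that the alignment
covers at least a minimum fraction of the flanking regions of both copies
— the flank-overlap filter that anchors two copies to one locus. Copies
whose alignment covers only the TE interior (same family, different
locus) fail this filter.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from collections import defaultdict

from .align import banded_local_align, chain_anchors, kmer_index, revcomp
from .config import PipelineConfig
from .copy_extraction import FlankedCopy
from .io_formats import AlignmentFragment, TECopy

__all__ = ["MatchEdge", "build_target_index", "align_extended_copies", "merge_collinear",
           "select_best_hits", "reciprocal_best_hits", "flank_overlap_filter",
           "match_genome_pair"]


@dataclass
class MatchEdge:
    """A validated reciprocal best hit between copies of two genomes.

    Flank coverages are the fractions of the left/right flank of each copy
    covered by the merged alignment span, in [0, 1]. An empty flank (a copy
    at a chromosome end with flank length 0) counts as fully covered.
    """

    accession_a: str
    copy_a_id: str
    accession_b: str
    copy_b_id: str
    total_score: float
    flank_cov_a_left: float
    flank_cov_a_right: float
    flank_cov_b_left: float
    flank_cov_b_right: float
    fragments: list[AlignmentFragment] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.accession_a == self.accession_b:
            raise ValueError("a match edge must join two different accessions")
        for cov in self.flank_coverages:
            if not (0.0 <= cov <= 1.0):
                raise ValueError("flank coverages must be in [0, 1]")

    @property
    def flank_coverages(self) -> tuple[float, float, float, float]:
        return (self.flank_cov_a_left, self.flank_cov_a_right,
                self.flank_cov_b_left, self.flank_cov_b_right)


# ---------------------------------------------------------------------------
# alignment
# ---------------------------------------------------------------------------

def _chrom_key(name: str, config: PipelineConfig) -> str:
    return config.chromosome_aliases.get(name, name)


def build_target_index(
    copies: list[FlankedCopy], config: PipelineConfig
) -> dict[str, dict[str, list[tuple[str, int]]]]:
    """Per-chromosome k-mer index over a genome's flank-extended copies:
    chromosome key -> k-mer -> [(copy_id, position), ...].

    Built once per genome and reused across all its pairings.
    """
    k = config.seed_k
    index: dict[str, dict[str, list[tuple[str, int]]]] = {}
    for fc in sorted(copies, key=lambda f: f.copy.copy_id):
        if fc.sequence is None:
            raise ValueError(f"copy {fc.copy.copy_id}: sequence not extracted")
        chrom = _chrom_key(fc.copy.chromosome, config)
        chrom_index = index.setdefault(chrom, {})
        cid = fc.copy.copy_id
        seq = fc.sequence
        for i in range(len(seq) - k + 1):
            kmer = seq[i : i + k]
            if "N" in kmer:
                continue
            chrom_index.setdefault(kmer, []).append((cid, i))
    return index


def align_extended_copies(
    copies_a: list[FlankedCopy],
    copies_b: list[FlankedCopy],
    config: PipelineConfig,
    paf_fragments: list[AlignmentFragment] | None = None,
    target_index: dict | None = None,
) -> list[AlignmentFragment]:
    """Align every eligible copy of genome A against copies of genome B.

    Built-in backend: exact k-mer seeding between each query and candidate
    targets (both orientations), collinear chaining, and banded affine-gap
    extension. With ``same_chromosome_only`` only copies on homonymous
    chromosomes are compared. When ``paf_fragments`` is given (external
    aligner mode) those fragments are returned filtered to known copy ids.
    """
    if paf_fragments is not None:
        ids_a = {fc.copy.copy_id for fc in copies_a}
        ids_b = {fc.copy.copy_id for fc in copies_b}
        return [f for f in paf_fragments
                if f.query_copy_id in ids_a and f.target_copy_id in ids_b]

    k = config.seed_k
    if target_index is None:
        target_index = build_target_index(copies_b, config)
    seq_b = {fc.copy.copy_id: fc.sequence for fc in copies_b}
    fragments: list[AlignmentFragment] = []

    for fc_a in sorted(copies_a, key=lambda f: f.copy.copy_id):
        qseq = fc_a.sequence
        if qseq is None:
            raise ValueError(f"copy {fc_a.copy.copy_id}: sequence not extracted")
        if config.same_chromosome_only:
            chrom_indexes = [target_index.get(_chrom_key(fc_a.copy.chromosome, config), {})]
        else:
            chrom_indexes = list(target_index.values())
        # accumulate anchors per candidate target, both orientations
        fwd: dict[str, list[tuple[int, int]]] = defaultdict(list)
        rev: dict[str, list[tuple[int, int]]] = defaultdict(list)
        n_q = len(qseq)
        for i in range(n_q - k + 1):
            kmer = qseq[i : i + k]
            if "N" in kmer:
                continue
            for chrom_index in chrom_indexes:
                hits = chrom_index.get(kmer)
                if hits:
                    for cid, tp in hits:
                        fwd[cid].append((i, tp))
                rhits = chrom_index.get(revcomp(kmer))
                if rhits:
                    for cid, tp in rhits:
                        # anchor between query and revcomp(target): the k-mer
                        # starting at tp ends at position len(t) - tp - k on
                        # the reverse complement
                        rev[cid].append((i, tp))
        for cid in sorted(set(fwd) | set(rev)):
            tseq = seq_b[cid]
            m = len(tseq)
            fwd_chain = chain_anchors(fwd.get(cid, []))
            rev_chain = chain_anchors([(qp, m - tp - k) for qp, tp in rev.get(cid, [])])
            if max(len(fwd_chain), len(rev_chain)) < config.min_seed_anchors:
                continue
            if len(fwd_chain) >= len(rev_chain):
                orientation, chain, tgt = "+", fwd_chain, tseq
            else:
                orientation, chain, tgt = "-", rev_chain, revcomp(tseq)
            diags = [t - q for q, t in chain]
            res = banded_local_align(
                qseq, tgt, min(diags) - config.band_pad, max(diags) + config.band_pad,
                config.match, config.mismatch, config.gap_open, config.gap_extend,
            )
            if res is None:
                continue
            ts, te = res["t_start"], res["t_end"]
            if orientation == "-":
                ts, te = m - res["t_end"], m - res["t_start"]
            fragments.append(
                AlignmentFragment(
                    query_copy_id=fc_a.copy.copy_id,
                    target_copy_id=cid,
                    q_start=res["q_start"],
                    q_end=res["q_end"],
                    t_start=ts,
                    t_end=te,
                    orientation=orientation,
                    score=res["score"],
                    identity_pct=res["identity_pct"],
                )
            )
    return fragments


# ---------------------------------------------------------------------------
# collinear merging
# ---------------------------------------------------------------------------

def merge_collinear(fragments: list[AlignmentFragment], merge_max_gap: int) -> list[AlignmentFragment]:
    """Merge nearby collinear fragments within each
    (query copy, target copy, orientation) group.

    Fragments sorted by query start are merged greedily while the next
    fragment starts after the current end on both query and target and both
    gaps are at most ``merge_max_gap``; merged score is the sum of member
    scores, merged span the union of member spans.
    """
    groups: dict[tuple[str, str, str], list[AlignmentFragment]] = {}
    for f in fragments:
        groups.setdefault((f.query_copy_id, f.target_copy_id, f.orientation), []).append(f)
    merged: list[AlignmentFragment] = []
    for key in sorted(groups):
        group = sorted(groups[key], key=lambda f: (f.q_start, f.t_start))
        current = None
        for f in group:
            if current is None:
                current = f
                continue
            q_gap = f.q_start - current.q_end
            t_gap = f.t_start - current.t_end
            if 0 <= q_gap <= merge_max_gap and 0 <= t_gap <= merge_max_gap:
                cols_cur = (current.q_end - current.q_start)
                cols_new = (f.q_end - f.q_start)
                ident = float("nan")
                if cols_cur + cols_new:
                    ident = (current.identity_pct * cols_cur + f.identity_pct * cols_new) / (cols_cur + cols_new)
                current = AlignmentFragment(
                    query_copy_id=current.query_copy_id,
                    target_copy_id=current.target_copy_id,
                    q_start=current.q_start,
                    q_end=f.q_end,
                    t_start=current.t_start,
                    t_end=f.t_end,
                    orientation=current.orientation,
                    score=current.score + f.score,
                    identity_pct=ident,
                )
            else:
                merged.append(current)
                current = f
        if current is not None:
            merged.append(current)
    return merged


# ---------------------------------------------------------------------------
# reciprocal best hits
# ---------------------------------------------------------------------------

def select_best_hits(
    matches: list[AlignmentFragment],
    copy_lookup: dict[str, TECopy],
    direction: str = "query",
) -> dict[str, AlignmentFragment]:
    """Best merged match per copy, by maximal total score.

    ``direction`` selects whether matches are grouped by their query
    (``"query"``, best hit of each A copy into B) or by their target
    (``"target"``, best hit of each B copy into A; scores are symmetric).
    Ties are broken by the (chromosome name, start) of the other copy,
    lexicographic ascending.
    """
    if direction not in ("query", "target"):
        raise ValueError("direction must be 'query' or 'target'")
    best: dict[str, AlignmentFragment] = {}
    for f in matches:
        own = f.query_copy_id if direction == "query" else f.target_copy_id
        other_id = f.target_copy_id if direction == "query" else f.query_copy_id
        other = copy_lookup[other_id]
        key = (-f.score, other.chromosome, other.start, other_id)
        incumbent = best.get(own)
        if incumbent is None:
            best[own] = f
            continue
        inc_other_id = incumbent.target_copy_id if direction == "query" else incumbent.query_copy_id
        inc_other = copy_lookup[inc_other_id]
        inc_key = (-incumbent.score, inc_other.chromosome, inc_other.start, inc_other_id)
        if key < inc_key:
            best[own] = f
    return best


def _flank_coverage(span_start: int, span_end: int, flanked: FlankedCopy) -> tuple[float, float]:
    """Coverage of the left/right flank intervals (in extended-sequence
    coordinates) by an alignment span. Empty flanks count as covered."""
    lf, rf = flanked.left_flank_len, flanked.right_flank_len
    L = flanked.extended_length
    def frac(lo: int, hi: int) -> float:
        if hi <= lo:
            return 1.0
        ov = max(0, min(span_end, hi) - max(span_start, lo))
        return ov / (hi - lo)
    return frac(0, lf), frac(L - rf, L)


def reciprocal_best_hits(
    best_a_to_b: dict[str, AlignmentFragment],
    best_b_to_a: dict[str, AlignmentFragment],
    flanked_a: dict[str, FlankedCopy],
    flanked_b: dict[str, FlankedCopy],
    accession_a: str,
    accession_b: str,
) -> list[MatchEdge]:
    """Keep pairs (a, b) where b is a's best hit and a is b's, attaching
    flank coverages computed from the merged alignment span."""
    edges: list[MatchEdge] = []
    for a_id in sorted(best_a_to_b):
        fa = best_a_to_b[a_id]
        b_id = fa.target_copy_id
        fb = best_b_to_a.get(b_id)
        if fb is None or fb.query_copy_id != a_id:
            continue
        cov_a = _flank_coverage(fa.q_start, fa.q_end, flanked_a[a_id])
        cov_b = _flank_coverage(fa.t_start, fa.t_end, flanked_b[b_id])
        edges.append(
            MatchEdge(
                accession_a=accession_a,
                copy_a_id=a_id,
                accession_b=accession_b,
                copy_b_id=b_id,
                total_score=fa.score,
                flank_cov_a_left=cov_a[0],
                flank_cov_a_right=cov_a[1],
                flank_cov_b_left=cov_b[0],
                flank_cov_b_right=cov_b[1],
                fragments=[fa],
            )
        )
    return edges


def flank_overlap_filter(edge: MatchEdge, config: PipelineConfig,
                         flanked_a: dict[str, FlankedCopy] | None = None,
                         flanked_b: dict[str, FlankedCopy] | None = None) -> bool:
    """Validate an edge by flank overlap (inclusive threshold).

    ``per_flank`` mode requires each of the four coverages to reach the
    threshold; ``combined`` mode pools covered flank bases over total flank
    bases of both copies (requires the flanked copies for the base counts).
    """
    if config.flank_overlap_mode == "per_flank":
        return all(cov >= config.flank_overlap_min for cov in edge.flank_coverages)
    if flanked_a is None or flanked_b is None:
        raise ValueError("combined mode needs the flanked copies")
    fa, fb = flanked_a[edge.copy_a_id], flanked_b[edge.copy_b_id]
    lengths = [fa.left_flank_len, fa.right_flank_len, fb.left_flank_len, fb.right_flank_len]
    total = sum(lengths)
    if total == 0:
        return True
    covered = sum(cov * ln for cov, ln in zip(edge.flank_coverages, lengths))
    return covered / total >= config.flank_overlap_min


# ---------------------------------------------------------------------------
# per-pair orchestration
# ---------------------------------------------------------------------------

def match_genome_pair(
    copies_a: list[FlankedCopy],
    copies_b: list[FlankedCopy],
    accession_a: str,
    accession_b: str,
    config: PipelineConfig,
    paf_fragments: list[AlignmentFragment] | None = None,
    target_index: dict | None = None,
) -> list[MatchEdge]:
    """Full matching for one genome pair: align, merge, reciprocal best
    hits, flank-overlap validation. Alignment scores are symmetric, so both
    best-hit directions are derived from one aligned fragment list."""
    fragments = align_extended_copies(copies_a, copies_b, config, paf_fragments,
                                      target_index=target_index)
    merged = merge_collinear(fragments, config.merge_max_gap)
    lookup_a = {fc.copy.copy_id: fc.copy for fc in copies_a}
    lookup_b = {fc.copy.copy_id: fc.copy for fc in copies_b}
    flanked_a = {fc.copy.copy_id: fc for fc in copies_a}
    flanked_b = {fc.copy.copy_id: fc for fc in copies_b}
    best_ab = select_best_hits(merged, lookup_b, direction="query")
    best_ba = select_best_hits(merged, lookup_a, direction="target")
    # re-key best_ba by the B copy and express as fragments B->A
    best_ba_by_b: dict[str, AlignmentFragment] = {}
    for b_id, frag in best_ba.items():
        best_ba_by_b[b_id] = frag
    # reciprocal_best_hits expects best_b_to_a keyed by B copy with
    # .query_copy_id naming the A copy, which merged fragments already do
    edges = reciprocal_best_hits(best_ab, best_ba_by_b, flanked_a, flanked_b,
                                 accession_a, accession_b)
    return [e for e in edges
            if flank_overlap_filter(e, config, flanked_a, flanked_b)]
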