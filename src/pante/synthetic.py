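"""Synthetic pangenomes with planted TE insertions and ground truth.

The simulator builds one random ancestral backbone per chromosome
(uniform A/C/G/T, so every locus has a unique flanking context), plants
each TE consensus at its loci in exactly the accessions of its sharing
set, then applies independent per-base substitutions to each accession's
whole sequence. It emits assemblies, coordinate-correct TE annotations
(each copy shifted by the insertions upstream of it) and a truth table of
sharing sets, so pipeline recovery can be scored exactly.

What this emulates: insertion presence/absence polymorphism on a shared
genomic background with point-mutation divergence. What it does not:
structural variation beyond the planted TEs (an optional mode adds random
background indels), TE nesting, target-site duplications, or LTR internal
structure. Optional translocation mode re-inserts a copy together with
its flanking backbone segment on a different chromosome in chosen
accessions, to exercise relocation flagging.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io_formats import GenomeAssembly, TEConsensus, TECopy

__all__ = ["PlantedTruth", "SimulatedPangenome", "AccuracyReport",
           "simulate_pangenome", "score_recovery", "annotation_accuracy"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_CLASSIFICATIONS = ("LTR/Copia", "LTR/Gypsy", "TIR/MuDR", "MITE",
                    "LINE", "SINE", "Helitron")


@dataclass
class PlantedTruth:
    """Ground truth for one planted insertion."""

    insertion_id: str
    consensus_id: str
    sharing: tuple  # accession ids carrying the insertion
    loci: dict     # accession -> (chromosome, start, end), final 0-based half-open
    mutation_rate: float

    def __post_init__(self) -> None:
        if not self.sharing:
            raise ValueError("sharing set must be non-empty")


@dataclass
class SimulatedPangenome:
    assemblies: dict          # accession -> GenomeAssembly
    copies: dict              # accession -> list[TECopy]
    library: dict             # consensus_id -> TEConsensus
    library_sequences: dict   # consensus_id -> str
    truth: list               # list[PlantedTruth]

    @property
    def accessions(self) -> list[str]:
        return list(self.assemblies)


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=length)]


def _to_str(arr: np.ndarray) -> str:
    return arr.tobytes().decode("ascii")


def simulate_pangenome(
    n_genomes: int,
    n_chromosomes: int = 2,
    chrom_len: int = 200_000,
    n_insertions: int = 50,
    mutation_rate: float = 0.01,
    seed: int = 0,
    te_library: dict[str, str] | None = None,
    n_families: int = 12,
    te_length_range: tuple[int, int] = (800, 3000),
    sharing_spec: list[list[int]] | None = None,
    sharing_size_range: tuple[int, int] | None = None,
    flank_bp: int = 500,
    translocations: dict[str, list[int]] | None = None,
    n_background_indels: int = 0,
    indel_max_len: int = 10,
    out_dir: str | Path | None = None,
) -> SimulatedPangenome:
    """Simulate a pangenome of ``n_genomes`` accessions with planted TEs.

    ``sharing_spec`` fixes the accession subset (indices) carrying each
    insertion; otherwise subset sizes are drawn uniformly from
    ``sharing_size_range`` (default 1..n_genomes) and members uniformly
    without replacement. Placements keep insertions separated by at least
    2 x flank_bp + max TE length + 200 bp so flanks never overlap;
    placements violating this are re-drawn, and a chromosome too small to
    host its share raises an error. All randomness flows from one
    generator seeded with ``seed``; identical calls are byte-identical.
    """
    rng = np.random.default_rng(seed)
    accessions = [f"acc{i:02d}" for i in range(n_genomes)]
    chrom_names = [f"chr{i + 1}" for i in range(n_chromosomes)]

    # TE library
    if te_library is None:
        te_library = {}
        for i in range(n_families):
            length = int(rng.integers(te_length_range[0], te_length_range[1] + 1))
            te_library[f"consensus_{i:02d}"] = _to_str(_random_seq(rng, length))
    library = {
        cid: TEConsensus(cid, len(seq), _CLASSIFICATIONS[i % len(_CLASSIFICATIONS)])
        for i, (cid, seq) in enumerate(te_library.items())
    }
    max_te_len = max(len(s) for s in te_library.values())
    spacing = 2 * flank_bp + max_te_len + 200
    margin = flank_bp + max_te_len + 200

    backbone = {name: _random_seq(rng, chrom_len) for name in chrom_names}

    # insertion loci on the ancestral backbone
    positions: dict[str, list[int]] = {name: [] for name in chrom_names}

    def place(chrom: str) -> int:
        for _ in range(2000):
            pos = int(rng.integers(margin, chrom_len - margin))
            if all(abs(pos - p) >= spacing for p in positions[chrom]):
                positions[chrom].append(pos)
                return pos
        raise ValueError(f"chromosome length {chrom_len} too small for the "
                         f"requested insertions (spacing {spacing})")

    consensus_ids = list(te_library)
    insertions = []  # (insertion_id, consensus_id, chrom, backbone_pos, carriers)
    for i in range(n_insertions):
        cid = consensus_ids[int(rng.integers(0, len(consensus_ids)))]
        chrom = chrom_names[int(rng.integers(0, n_chromosomes))]
        pos = place(chrom)
        if sharing_spec is not None:
            carriers = sorted(sharing_spec[i])
        else:
            lo, hi = sharing_size_range or (1, n_genomes)
            size = int(rng.integers(lo, hi + 1))
            carriers = sorted(rng.choice(n_genomes, size=size, replace=False).tolist())
        insertions.append((f"ins{i:03d}", cid, chrom, pos, carriers))

    # translocation destinations, one per translocated insertion
    translocations = translocations or {}
    trans_dest: dict[str, tuple[str, int]] = {}
    cassette_pad = flank_bp + 100
    for ins_id in sorted(translocations):
        src_chrom = next(ins[2] for ins in insertions if ins[0] == ins_id)
        others = [c for c in chrom_names if c != src_chrom] or chrom_names
        dest = others[int(rng.integers(0, len(others)))]
        trans_dest[ins_id] = (dest, place(dest))

    # realize every accession: splice events, then whole-genome substitutions
    assemblies: dict[str, GenomeAssembly] = {}
    copies: dict[str, list[TECopy]] = {}
    loci: dict[str, dict[str, tuple[str, int, int]]] = {ins[0]: {} for ins in insertions}

    for acc_idx, acc in enumerate(accessions):
        # events per chromosome: (backbone_pos, kind, payload, te_offset, te_len, ins_id)
        events: dict[str, list] = {name: [] for name in chrom_names}
        for ins_id, cid, chrom, pos, carriers in insertions:
            if acc_idx not in carriers:
                continue
            te_seq = te_library[cid]
            if acc_idx in translocations.get(ins_id, []):
                dest_chrom, dest_pos = trans_dest[ins_id]
                bb = backbone[chrom]
                cassette = (_to_str(bb[pos - cassette_pad:pos]) + te_seq
                            + _to_str(bb[pos:pos + cassette_pad]))
                events[dest_chrom].append(
                    (dest_pos, "ins", cassette, cassette_pad, len(te_seq), ins_id, cid))
            else:
                events[chrom].append((pos, "ins", te_seq, 0, len(te_seq), ins_id, cid))
        if n_background_indels:
            for _ in range(n_background_indels):
                chrom = chrom_names[int(rng.integers(0, n_chromosomes))]
                pos = int(rng.integers(100, chrom_len - 100))
                length = int(rng.integers(1, indel_max_len + 1))
                if rng.random() < 0.5:
                    events[chrom].append((pos, "ins", _to_str(_random_seq(rng, length)),
                                          None, 0, None, None))
                else:
                    events[chrom].append((pos, "del", length, None, 0, None, None))

        chrom_seqs: dict[str, str] = {}
        acc_copies: list[TECopy] = []
        te_spans: dict[str, list] = {}
        for chrom in chrom_names:
            bb = backbone[chrom]
            evs = sorted(events[chrom], key=lambda e: (e[0], str(e[5])))
            parts = []
            cursor = 0
            offset = 0
            spans = []
            for ev in evs:
                pos, kind = ev[0], ev[1]
                if pos < cursor:   # overlapping background indel; skip it
                    continue
                parts.append(bb[cursor:pos])
                if kind == "ins":
                    payload = np.frombuffer(ev[2].encode("ascii"), dtype=np.uint8)
                    if ev[5] is not None:
                        te_start = pos + offset + ev[3]
                        spans.append((ev[5], ev[6], te_start, te_start + ev[4]))
                    parts.append(payload)
                    offset += len(payload)
                    cursor = pos
                else:
                    cursor = pos + ev[2]
                    offset -= ev[2]
            parts.append(bb[cursor:])
            seq = np.concatenate(parts)
            # substitutions over the whole realized chromosome
            if mutation_rate > 0:
                mask = rng.random(seq.shape[0]) < mutation_rate
                idx = np.where(mask)[0]
                code = np.zeros(seq.shape[0], dtype=np.uint8)
                for b, c in zip(b"ACGT", range(4)):
                    code[seq == b] = c
                code[idx] = (code[idx] + rng.integers(1, 4, size=idx.shape[0])) % 4
                seq = _BASES[code]
            else:
                mask = np.zeros(seq.shape[0], dtype=bool)
            chrom_seqs[chrom] = _to_str(seq)
            for ins_id, cid, start, end in spans:
                identity = 100.0 * (1.0 - mask[start:end].mean())
                acc_copies.append(
                    TECopy(
                        copy_id=f"{acc}.{ins_id}",
                        accession_id=acc,
                        chromosome=chrom,
                        start=start,
                        end=end,
                        strand="+",
                        consensus_id=cid,
                        consensus_match_start=0,
                        consensus_match_end=library[cid].length,
                        identity_pct=float(identity),
                    )
                )
                loci[ins_id][acc] = (chrom, start, end)
        acc_copies.sort(key=lambda c: (c.chromosome, c.start))
        assemblies[acc] = GenomeAssembly(acc, chrom_seqs)
        copies[acc] = acc_copies

    truth = [
        PlantedTruth(
            insertion_id=ins_id,
            consensus_id=cid,
            sharing=tuple(accessions[i] for i in carriers),
            loci=loci[ins_id],
            mutation_rate=mutation_rate,
        )
        for ins_id, cid, _chrom, _pos, carriers in insertions
    ]
    sim = SimulatedPangenome(assemblies, copies, library, dict(te_library), truth)
    if out_dir is not None:
        _write_simulation(sim, Path(out_dir))
    return sim


def _write_simulation(sim: SimulatedPangenome, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "library.fa", "w") as fh:
        for cid, seq in sim.library_sequences.items():
            fh.write(f">{cid} {sim.library[cid].classification}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    for acc, asm in sim.assemblies.items():
        with open(out_dir / f"{acc}.fa", "w") as fh:
            for chrom, seq in asm.chromosomes.items():
                fh.write(f">{chrom}\n")
                for i in range(0, len(seq), 80):
                    fh.write(seq[i:i + 80] + "\n")
        with open(out_dir / f"{acc}.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for c in sim.copies[acc]:
                attrs = (f"ID={c.copy_id};Target={c.consensus_id} "
                         f"{c.consensus_match_start + 1} {c.consensus_match_end};"
                         f"Identity={c.identity_pct:.4f}")
                fh.write(f"{c.chromosome}\tpante_sim\ttransposable_element\t"
                         f"{c.start + 1}\t{c.end}\t.\t{c.strand}\t.\t{attrs}\n")
    rows = []
    for t in sim.truth:
        for acc in t.sharing:
            chrom, start, end = t.loci[acc]
            rows.append({"insertion_id": t.insertion_id, "consensus_id": t.consensus_id,
                         "accession": acc, "chromosome": chrom, "start": start,
                         "end": end, "mutation_rate": t.mutation_rate})
    pd.DataFrame(rows).to_csv(out_dir / "truth.tsv", sep="\t", index=False)


# ---------------------------------------------------------------------------
# recovery scoring
# ---------------------------------------------------------------------------

def score_recovery(truth: list[PlantedTruth], cliques, copies_by_key) -> pd.DataFrame:
    """Match each planted insertion to the clique maximizing locus overlap.

    A clique member counts as recovered for an insertion when its accession
    carries the insertion and its copy interval overlaps the true locus.
    Reports, per insertion, the best clique, the shared-accession
    proportion |common| / max(truth size, clique size), and the size
    difference clique - truth.
    """
    locus_lookup: dict[str, list] = {}
    for t in truth:
        for acc in t.sharing:
            chrom, start, end = t.loci[acc]
            locus_lookup.setdefault(acc, []).append((chrom, start, end, t.insertion_id))

    def find_insertion(copy) -> str | None:
        for chrom, start, end, ins_id in locus_lookup.get(copy.accession_id, ()):
            if chrom == copy.chromosome and copy.start < end and start < copy.end:
                return ins_id
        return None

    # per insertion: clique_id -> number of matching members
    votes: dict[str, dict[str, int]] = {t.insertion_id: {} for t in truth}
    clique_size = {}
    for cl in cliques:
        clique_size[cl.clique_id] = cl.size
        for member in cl.members:
            ins_id = find_insertion(copies_by_key[member])
            if ins_id is not None:
                counter = votes[ins_id]
                counter[cl.clique_id] = counter.get(cl.clique_id, 0) + 1

    rows = []
    for t in truth:
        counter = votes[t.insertion_id]
        if counter:
            best_id = max(counter, key=lambda cid: (counter[cid], -clique_size[cid], cid))
            common = counter[best_id]
            size = clique_size[best_id]
            proportion = common / max(len(t.sharing), size)
            delta = size - len(t.sharing)
        else:
            best_id, common, size, proportion, delta = None, 0, 0, 0.0, np.nan
        rows.append({"insertion_id": t.insertion_id, "truth_size": len(t.sharing),
                     "clique_id": best_id, "clique_size": size, "n_common": common,
                     "proportion": proportion, "delta": delta})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nucleotide-level annotation accuracy
# ---------------------------------------------------------------------------

@dataclass
class AccuracyReport:
    """Nucleotide-level confusion counts against a gold annotation.

    TP: predicted TE bases that are gold TE bases; FN: gold bases missed;
    FP: predicted bases falling in coding sequence; TN: coding bases not
    predicted as TE.
    """

    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def accuracy(self) -> float:
        total = self.tp + self.tn + self.fp + self.fn
        return (self.tp + self.tn) / total if total else float("nan")


def _normalize(intervals) -> dict[str, list[tuple[int, int]]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for iv in intervals:
        if len(iv) == 2:
            chrom, start, end = "", iv[0], iv[1]
        else:
            chrom, start, end = iv
        if end > start:
            by_chrom.setdefault(chrom, []).append((start, end))
    return {c: _merge(v) for c, v in by_chrom.items()}


def _merge(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[list[int]] = []
    for start, end in sorted(intervals):
        if merged and start <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], end)
        else:
            merged.append([start, end])
    return [(s, e) for s, e in merged]


def _total(by_chrom) -> int:
    return sum(e - s for ivs in by_chrom.values() for s, e in ivs)


def _intersection(a, b) -> int:
    total = 0
    for chrom, ivs_a in a.items():
        ivs_b = b.get(chrom, [])
        i = j = 0
        while i < len(ivs_a) and j < len(ivs_b):
            lo = max(ivs_a[i][0], ivs_b[j][0])
            hi = min(ivs_a[i][1], ivs_b[j][1])
            if hi > lo:
                total += hi - lo
            if ivs_a[i][1] <= ivs_b[j][1]:
                i += 1
            else:
                j += 1
    return total


def annotation_accuracy(predicted, gold, cds) -> AccuracyReport:
    """Nucleotide-level sensitivity/specificity/accuracy of a TE annotation.

    ``predicted``, ``gold`` and ``cds`` are iterables of (start, end) or
    (chromosome, start, end) intervals, 0-based half-open on a common
    coordinate system; gold TE bases and CDS bases must not overlap.
    """
    p, g, c = _normalize(predicted), _normalize(gold), _normalize(cds)
    if _intersection(g, c) > 0:
        raise ValueError("gold TE intervals overlap CDS intervals")
    tp = _intersection(p, g)
    fn = _total(g) - tp
    fp = _intersection(p, c)
    tn = _total(c) - fp
    return AccuracyReport(tp=tp, fp=fp, tn=tn, fn=fn)
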