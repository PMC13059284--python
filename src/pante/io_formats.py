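"""Readers and writers for the standard formats the pipeline touches.

Coordinate conventions are fixed once here: everything in memory is 0-based
half-open; GFF3 on disk is 1-based closed; BED and PAF are 0-based
half-open. TE annotations arrive as GFF3 features whose column-9 attributes
carry the consensus identity (``Target=<id> <cstart> <cend>``, 1-based on
the consensus) and the percent identity (``Identity=<pct>``); alternative
attribute keys can be mapped through the reader arguments.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import dendropy
import numpy as np
import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

__all__ = [
    "GenomeAssembly",
    "TEConsensus",
    "TECopy",
    "DistanceMatrix",
    "AlignmentFragment",
    "read_genome",
    "read_consensus_library",
    "read_te_gff3",
    "read_paf",
    "read_newick_distances",
    "read_cluster_table",
    "write_outputs",
    "read_cliques_tsv",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class GenomeAssembly:
    """One de novo assembly: an accession id and its chromosome sequences."""

    accession_id: str
    chromosomes: dict[str, str]  # name -> uppercase sequence, insertion-ordered

    def __post_init__(self) -> None:
        if not self.accession_id:
            raise ValueError("accession_id must be non-empty")

    def length(self, chromosome: str) -> int:
        return len(self.chromosomes[chromosome])


@dataclass(frozen=True)
class TEConsensus:
    """A consensus (reference) sequence representing one TE family."""

    consensus_id: str
    length: int
    classification: str = "unknown"

    def __post_init__(self) -> None:
        if self.length <= 0:
            raise ValueError(f"consensus {self.consensus_id}: length must be > 0")


@dataclass
class TECopy:
    """One annotated TE occurrence in one genome.

    Genomic and consensus coordinates are 0-based half-open.
    """

    copy_id: str
    accession_id: str
    chromosome: str
    start: int
    end: int
    strand: str
    consensus_id: str
    consensus_match_start: int
    consensus_match_end: int
    identity_pct: float

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"copy {self.copy_id}: invalid interval [{self.start},{self.end})")
        if self.strand not in ("+", "-"):
            raise ValueError(f"copy {self.copy_id}: strand must be + or -")

    @property
    def length(self) -> int:
        return self.end - self.start


class DistanceMatrix:
    """Symmetric pairwise distances (substitutions/site) between accessions."""

    def __init__(self, ids: list[str], d: np.ndarray):
        d = np.asarray(d, dtype=float)
        if d.shape != (len(ids), len(ids)):
            raise ValueError("distance matrix shape does not match id list")
        if not np.allclose(d, d.T):
            raise ValueError("distance matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0):
            raise ValueError("distance matrix must have zero diagonal")
        if (d < 0).any():
            raise ValueError("distances must be >= 0")
        self.ids = list(ids)
        self.d = d
        self._index = {a: i for i, a in enumerate(self.ids)}
        if len(self._index) != len(self.ids):
            raise ValueError("duplicate accession ids in distance matrix")

    def __contains__(self, accession: str) -> bool:
        return accession in self._index

    def distance(self, a: str, b: str) -> float:
        return float(self.d[self._index[a], self._index[b]])


@dataclass
class AlignmentFragment:
    """One aligned fragment between two flank-extended copies.

    Coordinates are 0-based half-open on the extended sequences; ``score``
    is the alignment score (built-in aligner) or the residue-match count
    (PAF column 10, external mode).
    """

    query_copy_id: str
    target_copy_id: str
    q_start: int
    q_end: int
    t_start: int
    t_end: int
    orientation: str  # '+' or '-'
    score: float
    identity_pct: float = float("nan")

    def __post_init__(self) -> None:
        if not (self.q_start < self.q_end and self.t_start < self.t_end):
            raise ValueError("fragment intervals must be non-empty")
        if self.score < 0:
            raise ValueError("fragment score must be >= 0")


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------

def read_genome(path: str | Path, accession_id: str | None = None) -> GenomeAssembly:
    """Read a FASTA assembly; sequences are uppercased, record order kept.

    ``accession_id`` defaults to the file stem.
    """
    path = Path(path)
    chromosomes: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in chromosomes:
            raise ValueError(f"{path}: duplicate chromosome name {rec.id!r}")
        chromosomes[rec.id] = str(rec.seq).upper()
    return GenomeAssembly(accession_id or path.stem, chromosomes)


def read_consensus_library(path: str | Path) -> dict[str, TEConsensus]:
    """Read a TE consensus library FASTA.

    The classification tag is taken from the second whitespace-separated
    token of the header when present (e.g. ``>RLC_1 LTR/Copia``), else from
    a ``#``-suffix in the id (RepeatMasker-style ``name#Class/Family``).
    """
    library: dict[str, TEConsensus] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        name, classification = rec.id, "unknown"
        if "#" in rec.id:
            name, classification = rec.id.split("#", 1)
        else:
            tokens = rec.description.split()
            if len(tokens) > 1:
                classification = tokens[1]
        if name in library:
            raise ValueError(f"duplicate consensus id {name!r} in library")
        library[name] = TEConsensus(name, len(rec.seq), classification)
    return library


# ---------------------------------------------------------------------------
# GFF3
# ---------------------------------------------------------------------------

_TARGET_RE = re.compile(r"^(\S+)\s+(\d+)\s+(\d+)")


def _parse_attributes(col9: str) -> dict[str, str]:
    out = {}
    for item in col9.strip().split(";"):
        if not item:
            continue
        key, _, value = item.partition("=")
        out[key.strip()] = value.strip()
    return out


def read_te_gff3(
    path: str | Path,
    accession_id: str,
    assembly: GenomeAssembly | None = None,
    target_key: str = "Target",
    identity_key: str = "Identity",
) -> list[TECopy]:
    """Read a TE annotation GFF3 into :class:`TECopy` records.

    GFF3 coordinates (1-based closed) are converted to 0-based half-open.
    Features lacking a consensus id are skipped with a logged warning.
    Output is sorted by (chromosome, start).
    """
    path = Path(path)
    copies: list[TECopy] = []
    skipped = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) < 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, got {len(cols)}")
            chrom, _source, _type, start1, end1, _score, strand, _phase, attrs = cols[:9]
            start1, end1 = int(start1), int(end1)
            if start1 > end1:
                raise ValueError(f"{path}:{lineno}: start > end")
            attributes = _parse_attributes(attrs)
            target = attributes.get(target_key)
            if target is None or not _TARGET_RE.match(target):
                skipped += 1
                continue
            m = _TARGET_RE.match(target)
            consensus_id, cstart1, cend1 = m.group(1), int(m.group(2)), int(m.group(3))
            identity = float(attributes.get(identity_key, "nan"))
            if assembly is not None and chrom not in assembly.chromosomes:
                raise ValueError(f"{path}:{lineno}: unknown chromosome {chrom!r}")
            copy_id = attributes.get("ID", f"{accession_id}.{chrom}.{lineno}")
            copies.append(
                TECopy(
                    copy_id=copy_id,
                    accession_id=accession_id,
                    chromosome=chrom,
                    start=start1 - 1,
                    end=end1,
                    strand=strand if strand in ("+", "-") else "+",
                    consensus_id=consensus_id,
                    consensus_match_start=cstart1 - 1,
                    consensus_match_end=cend1,
                    identity_pct=identity,
                )
            )
    if skipped:
        logger.warning("%s: skipped %d feature(s) without a consensus id", path, skipped)
    copies.sort(key=lambda c: (c.chromosome, c.start, c.end, c.copy_id))
    return copies


# ---------------------------------------------------------------------------
# PAF (external-aligner mode)
# ---------------------------------------------------------------------------

def read_paf(path: str | Path) -> list[AlignmentFragment]:
    """Read a PAF file into alignment fragments.

    Query/target names are taken as copy ids; the residue-match count
    (column 10) is the fragment score; identity is matches / block length.
    """
    path = Path(path)
    fragments: list[AlignmentFragment] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            cols = line.split("\t")
            if len(cols) < 12:
                raise ValueError(f"{path}:{lineno}: PAF requires >= 12 columns, got {len(cols)}")
            qname, _qlen, qs, qe, strand, tname, _tlen, ts, te = cols[0], cols[1], cols[2], cols[3], cols[4], cols[5], cols[6], cols[7], cols[8]
            matches, block = int(cols[9]), int(cols[10])
            fragments.append(
                AlignmentFragment(
                    query_copy_id=qname,
                    target_copy_id=tname,
                    q_start=int(qs),
                    q_end=int(qe),
                    t_start=int(ts),
                    t_end=int(te),
                    orientation=strand,
                    score=float(matches),
                    identity_pct=100.0 * matches / block if block else float("nan"),
                )
            )
    return fragments


# ---------------------------------------------------------------------------
# Newick -> patristic distances
# ---------------------------------------------------------------------------

def read_newick_distances(path: str | Path) -> DistanceMatrix:
    """Patristic (path-sum) pairwise distances between the leaves of a tree."""
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick")
    except dendropy.dataio.newickreader.NewickReader.NewickReaderDuplicateTaxonError as exc:
        raise ValueError(f"duplicate leaf labels in tree: {exc}") from exc
    labels = [lf.taxon.label for lf in tree.leaf_node_iter()]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate leaf labels in tree")
    for edge in tree.preorder_edge_iter():
        if edge.head_node is tree.seed_node:
            continue
        if edge.length is None:
            raise ValueError("tree has a branch without a length")
        if edge.length < 0:
            raise ValueError("tree has a negative branch length")
    pdm = tree.phylogenetic_distance_matrix()
    taxa = {t.label: t for t in tree.taxon_namespace}
    ids = sorted(labels)
    n = len(ids)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = pdm.patristic_distance(taxa[ids[i]], taxa[ids[j]])
    return DistanceMatrix(ids, d)


def read_cluster_table(path: str | Path) -> dict[str, str]:
    """Read an accession -> genetic-cluster TSV (two columns, no header or
    header line starting with '#')."""
    table = pd.read_csv(path, sep="\t", header=None, comment="#", dtype=str)
    return dict(zip(table[0], table[1]))


# ---------------------------------------------------------------------------
# result writers
# ---------------------------------------------------------------------------

def _member_key(accession: str, copy) -> str:
    return f"{accession}:{copy.chromosome}:{copy.start}-{copy.end}"


def write_outputs(cliques, copies_by_key, out_dir: str | Path, accessions: list[str]) -> dict[str, Path]:
    """Write the clique table, the presence/absence matrix, and per-accession
    BED files of member copies.

    Parameters
    ----------
    cliques : list of InsertionClique (classification complete)
    copies_by_key : map (accession, copy_id) -> TECopy
    accessions : column order of the presence/absence matrix
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for cl in cliques:
        members = sorted(cl.members)
        locus = ",".join(
            _member_key(acc, copies_by_key[(acc, cid)]) for acc, cid in members
        )
        member_ids = ",".join(f"{acc}:{cid}" for acc, cid in members)
        rows.append(
            {
                "clique_id": cl.clique_id,
                "members": member_ids,
                "loci": locus,
                "size": cl.size,
                "compartment": cl.compartment,
                "age_kya": "" if cl.age_kya is None else f"{cl.age_kya:.6g}",
                "category": cl.category or "",
            }
        )
    cliques_tsv = out_dir / "cliques.tsv"
    pd.DataFrame(
        rows,
        columns=["clique_id", "members", "loci", "size", "compartment", "age_kya", "category"],
    ).to_csv(cliques_tsv, sep="\t", index=False)

    matrix = np.zeros((len(cliques), len(accessions)), dtype=int)
    acc_index = {a: i for i, a in enumerate(accessions)}
    for i, cl in enumerate(cliques):
        for acc, _cid in cl.members:
            matrix[i, acc_index[acc]] = 1
    matrix_tsv = out_dir / "presence_absence.tsv"
    pd.DataFrame(
        matrix, index=[cl.clique_id for cl in cliques], columns=accessions
    ).to_csv(matrix_tsv, sep="\t", index_label="clique_id")

    bed_paths = {}
    clique_of_copy: dict[tuple[str, str], list[str]] = {}
    for cl in cliques:
        for member in cl.members:
            clique_of_copy.setdefault(member, []).append(cl.clique_id)
    for acc in accessions:
        bed = out_dir / f"{acc}.copies.bed"
        with open(bed, "w") as fh:
            acc_copies = sorted(
                (key for key in copies_by_key if key[0] == acc),
                key=lambda key: (copies_by_key[key].chromosome, copies_by_key[key].start),
            )
            for key in acc_copies:
                copy = copies_by_key[key]
                ids = clique_of_copy.get(key)
                if ids is None:
                    name = "singleton"
                else:
                    shared = [i for i in ids if not i.startswith("singleton")]
                    name = ";".join(shared) if shared else "singleton"
                fh.write(
                    f"{copy.chromosome}\t{copy.start}\t{copy.end}\t{name}\t.\t{copy.strand}\n"
                )
        bed_paths[acc] = bed
    return {"cliques": cliques_tsv, "matrix": matrix_tsv, **bed_paths}


def read_cliques_tsv(path: str | Path) -> pd.DataFrame:
    """Read back a clique table written by :func:`write_outputs`."""
    return pd.read_csv(path, sep="\t", dtype={"age_kya": float}, keep_default_na=False,
                       na_values={"age_kya": [""]})
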