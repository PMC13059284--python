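"""Full-length copy selection and flank extension.

A copy is kept when its consensus coverage (``covcons``: aligned span on
the consensus divided by consensus length, x100) falls inside a closed
window, 95-105% by default — complete copies with small divergence from
their family consensus. Retained copies are then extended by a fixed
genomic flank on each side (clamped at chromosome bounds); the flanks
anchor the copy to its locus during cross-genome matching.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

from .config import PipelineConfig
from .io_formats import GenomeAssembly, TEConsensus, TECopy

__all__ = ["FlankedCopy", "compute_covcons", "select_copies", "extend_flanks",
           "extract_flanked_sequence", "extract_all"]


@dataclass
class FlankedCopy:
    """A TE copy extended by flanking intervals.

    ``extended_start``/``extended_end`` are the clamped coordinates of the
    copy plus flanks; the sequence (always forward strand) is attached by
    :func:`extract_flanked_sequence`.
    """

    copy: TECopy
    extended_start: int
    extended_end: int
    left_flank_len: int
    right_flank_len: int
    sequence: str | None = None
    short_flank: bool = False  # < 50% of the requested flank on a side

    @property
    def extended_length(self) -> int:
        return self.extended_end - self.extended_start


def compute_covcons(copy: TECopy, library: Mapping[str, TEConsensus]) -> float:
    """Percent of the consensus covered by the copy's aligned span.

    May exceed 100 when the copy is longer than its consensus (e.g. an
    internal insertion).
    """
    if copy.consensus_id not in library:
        raise KeyError(f"consensus {copy.consensus_id!r} not in library")
    consensus = library[copy.consensus_id]
    span = copy.consensus_match_end - copy.consensus_match_start
    return 100.0 * span / consensus.length


def select_copies(
    copies: Iterable[TECopy],
    library: Mapping[str, TEConsensus],
    config: PipelineConfig,
) -> list[TECopy]:
    """Retain copies whose covcons lies in the closed window
    [covcons_min, covcons_max]; input order preserved."""
    return [
        c
        for c in copies
        if config.covcons_min <= compute_covcons(c, library) <= config.covcons_max
    ]


def extend_flanks(copy: TECopy, flank_bp: int, chrom_length: int) -> FlankedCopy:
    """Symmetric coordinate extension clamped to [0, chrom_length].

    Records the flank actually obtained on each side; a copy retaining less
    than half the requested flank on either side is flagged.
    """
    extended_start = max(0, copy.start - flank_bp)
    extended_end = min(chrom_length, copy.end + flank_bp)
    left = copy.start - extended_start
    right = extended_end - copy.end
    short = flank_bp > 0 and (left < flank_bp / 2 or right < flank_bp / 2)
    return FlankedCopy(copy, extended_start, extended_end, left, right, short_flank=short)


def extract_flanked_sequence(assembly: GenomeAssembly, flanked: FlankedCopy) -> FlankedCopy:
    """Attach the forward-strand sequence of the extended interval.

    The copy's strand is kept as metadata only; minus-strand copies get the
    same forward-strand slice.
    """
    chrom = flanked.copy.chromosome
    if chrom not in assembly.chromosomes:
        raise KeyError(f"chromosome {chrom!r} not in assembly {assembly.accession_id}")
    seq = assembly.chromosomes[chrom]
    if not (0 <= flanked.extended_start <= flanked.extended_end <= len(seq)):
        raise ValueError(
            f"extended interval [{flanked.extended_start},{flanked.extended_end}) "
            f"out of bounds for {chrom} (length {len(seq)})"
        )
    flanked.sequence = seq[flanked.extended_start:flanked.extended_end]
    return flanked


def extract_all(
    assembly: GenomeAssembly,
    copies: Iterable[TECopy],
    library: Mapping[str, TEConsensus],
    config: PipelineConfig,
) -> list[FlankedCopy]:
    """Select full-length copies, extend and extract their sequences."""
    out = []
    for copy in select_copies(copies, library, config):
        flanked = extend_flanks(copy, config.flank_bp, assembly.length(copy.chromosome))
        if flanked.short_flank and not config.keep_short_flanks:
            continue
        out.append(extract_flanked_sequence(assembly, flanked))
    return out
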