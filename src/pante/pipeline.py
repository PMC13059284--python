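"""End-to-end orchestration: extract -> match -> cliques -> date.

Pairwise genome comparisons are independent of one another and of the
clique step, so pairs can be computed in separate invocations (or cached)
and combined later; adding a genome only requires its new pairs. All
stages iterate accessions in sorted order, which makes results invariant
to input order.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

from .cliques import (InsertionClique, build_insertion_graph, classify_compartments,
                      enumerate_maximal_cliques, flag_relocations)
from .config import PipelineConfig
from .copy_extraction import FlankedCopy, extract_all
from .dating import date_cliques
from .io_formats import DistanceMatrix, GenomeAssembly, TECopy, TEConsensus
from .matching import MatchEdge, build_target_index, match_genome_pair

__all__ = ["PipelineResult", "extract_stage", "match_stage", "clique_stage",
           "run_pipeline"]


@dataclass
class PipelineResult:
    accessions: list
    flanked: dict                    # accession -> list[FlankedCopy]
    copies_by_key: dict              # (accession, copy_id) -> TECopy
    edges: dict                      # (acc_a, acc_b) sorted pair -> list[MatchEdge]
    cliques: list                    # list[InsertionClique], classified

    @property
    def n_shared(self) -> int:
        return sum(1 for c in self.cliques if c.size >= 2)

    @property
    def n_singletons(self) -> int:
        return sum(1 for c in self.cliques if c.size == 1)

    def compartment_counts(self) -> dict:
        counts: dict[str, int] = {}
        for c in self.cliques:
            counts[c.compartment] = counts.get(c.compartment, 0) + 1
        return counts


def extract_stage(
    assemblies: dict[str, GenomeAssembly],
    copies: dict[str, list[TECopy]],
    library: dict[str, TEConsensus],
    config: PipelineConfig,
) -> dict[str, list[FlankedCopy]]:
    """Select full-length copies and extract flank-extended sequences for
    every accession."""
    return {
        acc: extract_all(assemblies[acc], copies.get(acc, []), library, config)
        for acc in sorted(assemblies)
    }


def match_stage(
    flanked: dict[str, list[FlankedCopy]],
    config: PipelineConfig,
    pairs: list[tuple[str, str]] | None = None,
) -> dict[tuple[str, str], list[MatchEdge]]:
    """Validated reciprocal-best-hit edges for every (or the given)
    unordered accession pairs."""
    accessions = sorted(flanked)
    if pairs is None:
        pairs = list(combinations(accessions, 2))
    indexes = {acc: build_target_index(flanked[acc], config) for acc in accessions}
    edges: dict[tuple[str, str], list[MatchEdge]] = {}
    for a, b in pairs:
        a, b = sorted((a, b))
        edges[(a, b)] = match_genome_pair(
            flanked[a], flanked[b], a, b, config, target_index=indexes[b]
        )
    return edges


def clique_stage(
    edges: dict[tuple[str, str], list[MatchEdge]] | list[MatchEdge],
    flanked: dict[str, list[FlankedCopy]],
    config: PipelineConfig,
    n_accessions: int | None = None,
) -> tuple[list[InsertionClique], dict]:
    """Build the insertion graph over all extracted copies, enumerate
    maximal cliques and classify compartments."""
    if isinstance(edges, dict):
        edge_list = [e for key in sorted(edges) for e in edges[key]]
    else:
        edge_list = list(edges)
    copies_by_key = {
        (acc, fc.copy.copy_id): fc.copy
        for acc in sorted(flanked) for fc in flanked[acc]
    }
    graph = build_insertion_graph(edge_list, nodes=sorted(copies_by_key))
    cliques = enumerate_maximal_cliques(graph)
    n = n_accessions if n_accessions is not None else len(flanked)
    classify_compartments(cliques, n, config)
    flag_relocations(cliques, copies_by_key)
    return cliques, copies_by_key


def run_pipeline(
    assemblies: dict[str, GenomeAssembly],
    copies: dict[str, list[TECopy]],
    library: dict[str, TEConsensus],
    config: PipelineConfig,
    distances: DistanceMatrix | None = None,
    clusters: dict[str, str] | None = None,
) -> PipelineResult:
    """Run the full pipeline; dating happens when a distance matrix is
    supplied."""
    flanked = extract_stage(assemblies, copies, library, config)
    edges = match_stage(flanked, config)
    cliques, copies_by_key = clique_stage(edges, flanked, config)
    if distances is not None:
        date_cliques(cliques, distances, len(assemblies), config, clusters)
    return PipelineResult(
        accessions=sorted(assemblies),
        flanked=flanked,
        copies_by_key=copies_by_key,
        edges=edges,
        cliques=cliques,
    )
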