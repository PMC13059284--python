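"""Shared-insertion graph, maximal cliques, and pangenome compartments.

Validated reciprocal best hits form an undirected graph whose nodes are TE
copies. A maximal clique — a complete subgraph that cannot be extended —
is taken as a proxy for one insertion event present at the same locus in
several genomes. Because edges never join two copies of the same
accession, no clique can contain two copies from one genome. Cliques are
binned into pangenome compartments by sharing size: singleton (1), cloud
(few), shell (intermediate), soft-core (nearly all) and core (all
accessions); the cloud/shell and shell/soft-core boundaries are floors of
configurable panel fractions (20% and 95% by default), which for a panel
of 42 accessions gives cloud 2-7, shell 8-38, soft-core 39-41, core 42.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import networkx as nx

from .config import PipelineConfig
from .io_formats import TECopy
from .matching import MatchEdge

__all__ = ["InsertionClique", "build_insertion_graph", "enumerate_maximal_cliques",
           "classify_compartments", "flag_relocations", "compartment_of_size",
           "compartment_boundaries"]

Member = tuple[str, str]  # (accession_id, copy_id)


@dataclass
class InsertionClique:
    """One shared insertion: a maximal clique of matched copies."""

    clique_id: str
    members: frozenset
    compartment: str | None = None
    relocation_flag: bool = False
    max_distance: float | None = None
    age_kya: float | None = None
    category: str | None = None

    def __post_init__(self) -> None:
        accessions = {acc for acc, _ in self.members}
        if len(accessions) != len(self.members):
            raise ValueError(f"clique {self.clique_id}: two copies from one accession")

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def accessions(self) -> set[str]:
        return {acc for acc, _ in self.members}


def build_insertion_graph(
    edges: Iterable[MatchEdge],
    nodes: Iterable[Member] = (),
) -> nx.Graph:
    """Simple undirected graph: copies as (accession, copy_id) nodes, RBH
    edges between them. ``nodes`` declares copies with no edge (isolated
    nodes become singletons downstream). Duplicate edges collapse silently;
    an edge within one accession is rejected."""
    graph = nx.Graph()
    graph.add_nodes_from(nodes)
    for e in edges:
        if e.accession_a == e.accession_b:
            raise ValueError("edge joins two copies of one accession")
        graph.add_edge((e.accession_a, e.copy_a_id), (e.accession_b, e.copy_b_id))
    return graph


def enumerate_maximal_cliques(graph: nx.Graph) -> list[InsertionClique]:
    """All maximal cliques (Bron-Kerbosch with pivoting, via networkx).

    A node may appear in several cliques when its copy has diverged between
    groups of genomes. Isolated nodes yield size-1 singleton cliques.
    Output is deterministic: members sorted within a clique, cliques sorted
    by member lists, ids assigned in that order (``clique_N`` for shared
    insertions, ``singleton_N`` for size 1).
    """
    raw = [tuple(sorted(c)) for c in nx.find_cliques(graph)]
    raw.sort()
    cliques = []
    n_shared = n_single = 0
    for members in raw:
        if len(members) == 1:
            n_single += 1
            cid = f"singleton_{n_single:06d}"
        else:
            n_shared += 1
            cid = f"clique_{n_shared:06d}"
        cliques.append(InsertionClique(cid, frozenset(members)))
    return cliques


def compartment_boundaries(n_accessions: int, config: PipelineConfig) -> tuple[int, int]:
    """(cloud_max, softcore_min): the smallest shell size and the smallest
    soft-core size, floors of the configured panel fractions."""
    if n_accessions < 2:
        raise ValueError("need at least 2 accessions to define compartments")
    cloud_max = int(config.cloud_max_frac * n_accessions)
    softcore_min = int(config.softcore_min_frac * n_accessions)
    return cloud_max, softcore_min


def compartment_of_size(size: int, n_accessions: int, config: PipelineConfig) -> str:
    cloud_max, softcore_min = compartment_boundaries(n_accessions, config)
    if size <= 0 or size > n_accessions:
        raise ValueError(f"clique size {size} outside [1, {n_accessions}]")
    if size == 1:
        return "singleton"
    if size == n_accessions:
        return "core"
    if size >= softcore_min:
        return "soft_core"
    if size >= cloud_max:
        return "shell"
    return "cloud"


def classify_compartments(
    cliques: list[InsertionClique], n_accessions: int, config: PipelineConfig
) -> list[InsertionClique]:
    """Label every clique with its pangenome compartment (in place)."""
    for cl in cliques:
        cl.compartment = compartment_of_size(cl.size, n_accessions, config)
    return cliques


def flag_relocations(
    cliques: list[InsertionClique], copies_by_key: dict[Member, TECopy]
) -> list[InsertionClique]:
    """Flag cliques whose members occupy two or more chromosome names —
    candidate inter-chromosomal translocations or segmental duplications.
    Only informative when matching was not restricted to homonymous
    chromosomes."""
    for cl in cliques:
        chroms = {copies_by_key[m].chromosome for m in cl.members}
        cl.relocation_flag = len(chroms) >= 2
    return cliques
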