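"""Insertion dating from pairwise SNP distances.

An insertion shared by a set of accessions must predate their divergence,
so its age is approximated — as a lower bound — by the maximum pairwise
SNP-based genetic distance (substitutions/site) between any two carriers.
Distances convert linearly to thousands of years through a two-point
calibration: a species-specific pairwise distance asserted to correspond
to a dated split (default 0.1549 substitutions/site = 23 kya, the
S+/T+ lineage split of Brachypodium distachyon).

Dated insertions fall into four historical categories, evaluated in
precedence order with an explicit leftover bucket:

(ii)  ancient_conserved   — shared by nearly the whole panel;
(iv)  post_divergence     — carriers confined to one genetic cluster;
(iii) recent              — few carriers, all genetically close;
(i)   ancient_not_conserved — carriers genetically distant;
      unclassified        — none of the above.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

from .cliques import InsertionClique
from .config import PipelineConfig
from .io_formats import DistanceMatrix, TECopy

logger = logging.getLogger(__name__)

__all__ = ["AgeEstimate", "clique_max_distance", "distance_to_age",
           "categorize_insertion", "classify_recent_singletons", "date_cliques"]


@dataclass
class AgeEstimate:
    clique_id: str
    max_pairwise_distance: float
    age_kya: float
    category: str = "unclassified"


def clique_max_distance(clique: InsertionClique, distances: DistanceMatrix) -> float:
    """Maximum pairwise SNP distance between any two member accessions."""
    accs = sorted(clique.accessions)
    if len(accs) < 2:
        raise ValueError(f"clique {clique.clique_id}: dating needs >= 2 accessions")
    for a in accs:
        if a not in distances:
            raise KeyError(f"accession {a!r} missing from distance matrix")
    return max(
        distances.distance(a, b) for i, a in enumerate(accs) for b in accs[i + 1:]
    )


def distance_to_age(d: float, config: PipelineConfig) -> float:
    """Linear conversion of SNP distance to kya via the calibration pair."""
    if d < 0:
        raise ValueError("distance must be >= 0")
    return d * config.calibration_age / config.calibration_distance


def categorize_insertion(
    clique: InsertionClique,
    age_estimate: AgeEstimate,
    clusters: dict[str, str] | None,
    n_accessions: int,
    config: PipelineConfig,
) -> str:
    """Assign one of the four historical categories (precedence order)."""
    size = clique.size
    d = age_estimate.max_pairwise_distance
    if size >= math.ceil(config.conserved_min_fraction * n_accessions):
        return "ancient_conserved"
    if clusters is not None:
        labels = {clusters.get(acc) for acc in clique.accessions}
        if None in labels:
            logger.warning(
                "clique %s: accession(s) without a cluster label; "
                "post-divergence test skipped", clique.clique_id
            )
        elif len(labels) == 1:
            return "post_divergence"
    if size <= config.recent_max_accessions and d < config.ancient_distance_threshold:
        return "recent"
    if d > config.ancient_distance_threshold:
        return "ancient_not_conserved"
    return "unclassified"


def date_cliques(
    cliques: list[InsertionClique],
    distances: DistanceMatrix,
    n_accessions: int,
    config: PipelineConfig,
    clusters: dict[str, str] | None = None,
) -> list[AgeEstimate]:
    """Date and categorize every shared clique (size >= 2), annotating the
    cliques in place; singletons are left undated."""
    estimates = []
    for cl in cliques:
        if cl.size < 2:
            continue
        d = clique_max_distance(cl, distances)
        est = AgeEstimate(cl.clique_id, d, distance_to_age(d, config))
        est.category = categorize_insertion(cl, est, clusters, n_accessions, config)
        cl.max_distance = d
        cl.age_kya = est.age_kya
        cl.category = est.category
        estimates.append(est)
    return estimates


def classify_recent_singletons(
    copies: list[TECopy],
    singleton_keys: set[tuple[str, str]],
    cliques: list[InsertionClique],
    config: PipelineConfig,
) -> tuple[list[TECopy], list[InsertionClique]]:
    """Two proxies for recent transposition activity.

    Returns (a) singleton copies with identity to their consensus strictly
    above the threshold (default > 95%), and (b) dated cliques younger than
    the Holocene cutoff (default < 7.5 kya).
    """
    recent_singletons = [
        c for c in copies
        if (c.accession_id, c.copy_id) in singleton_keys
        and c.identity_pct > config.recent_identity_min
    ]
    post_holocene = [
        cl for cl in cliques
        if cl.age_kya is not None and cl.age_kya < config.holocene_age
    ]
    return recent_singletons, post_holocene
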