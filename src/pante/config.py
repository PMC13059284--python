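"""Pipeline configuration.

All thresholds and calibration constants of the pipeline live in a single
:class:`PipelineConfig` so that a run is fully described by one object.
Defaults correspond to the standard operating point for an intra-specific
panel of de novo assemblies: full-length copies only (covcons 95-105%),
500 bp flank anchors, an 80% flank-overlap validation, and a two-point
molecular calibration of SNP distance against a dated lineage split.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """Thresholds and constants controlling every pipeline stage.

    Parameters
    ----------
    covcons_min, covcons_max : float
        Inclusive bounds (percent) on consensus coverage for a copy to be
        considered full-length. Coverage above 100% is possible when a copy
        is longer than its consensus.
    flank_bp : int
        Genomic flank appended on each side of a copy before alignment;
        the flanks anchor a copy to its locus.
    flank_overlap_min : float
        Minimum fraction of each flank that the validated alignment must
        cover (inclusive). ``flank_overlap_mode`` selects whether the four
        flank coverages are tested individually (``"per_flank"``) or pooled
        (``"combined"``: total covered flank bases / total flank bases).
    same_chromosome_only : bool
        Compare copies only between homonymous chromosomes.
    merge_max_gap : int
        Maximum gap (bp, on both query and target) bridged when merging
        collinear alignment fragments.
    seed_k : int
        Exact k-mer length used for seeding the built-in aligner.
    match, mismatch, gap_open, gap_extend : int
        Affine-gap scores of the built-in aligner.
    min_seed_anchors : int
        Minimum number of shared k-mers for a copy pair to be aligned.
    calibration_distance, calibration_age : float
        The two-point molecular calibration: a pairwise SNP distance
        (substitutions/site) asserted to correspond to ``calibration_age``
        thousand years. Species-specific.
    ancient_distance_threshold : float
        SNP distance (substitutions/site) separating "recent" from
        "ancient" insertion categories.
    conserved_min_fraction : float
        Minimum fraction of the panel an insertion must reach to be called
        ancient-and-conserved (ceil of fraction x N accessions).
    recent_max_accessions : int
        Maximum sharing size for the "recent" category.
    recent_identity_min : float
        Identity (%) above which a singleton counts as a recent insertion
        (strict inequality).
    holocene_age : float
        Age (kya) below which a dated insertion is flagged post-Holocene.
    cloud_max_frac, softcore_min_frac : float
        Pangenome compartment boundaries as fractions of the panel size;
        boundaries are floors of fraction x N.
    keep_short_flanks : bool
        Keep copies that retained less than half the requested flank on a
        side (they are flagged either way).
    random_seed : int
        Seed for every stochastic component.
    """

    covcons_min: float = 95.0
    covcons_max: float = 105.0
    flank_bp: int = 500
    flank_overlap_min: float = 0.80
    flank_overlap_mode: str = "per_flank"  # or "combined"
    same_chromosome_only: bool = True
    chromosome_aliases: dict = field(default_factory=dict)
    merge_max_gap: int = 500
    seed_k: int = 15
    match: int = 2
    mismatch: int = -3
    gap_open: int = -5
    gap_extend: int = -2
    min_seed_anchors: int = 4
    band_pad: int = 24
    calibration_distance: float = 0.1549
    calibration_age: float = 23.0
    ancient_distance_threshold: float = 0.20
    conserved_min_fraction: float = 37.0 / 42.0
    recent_max_accessions: int = 6
    recent_identity_min: float = 95.0
    holocene_age: float = 7.5
    cloud_max_frac: float = 0.20
    softcore_min_frac: float = 0.95
    keep_short_flanks: bool = True
    random_seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.covcons_min <= self.covcons_max):
            raise ValueError("require 0 < covcons_min <= covcons_max")
        if self.flank_bp < 0:
            raise ValueError("flank_bp must be >= 0")
        if not (0 < self.flank_overlap_min <= 1):
            raise ValueError("flank_overlap_min must be in (0, 1]")
        if self.flank_overlap_mode not in ("per_flank", "combined"):
            raise ValueError("flank_overlap_mode must be 'per_flank' or 'combined'")
        if self.calibration_distance <= 0:
            raise ValueError("calibration_distance must be > 0")
        if self.seed_k < 4:
            raise ValueError("seed_k must be >= 4")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)
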