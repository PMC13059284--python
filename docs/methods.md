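# Methods

## Model of a shared insertion

A TE insertion event deposits one copy at one genomic locus in one
ancestor; descendants inherit the copy together with its flanking
sequence. Two copies in two genomes therefore represent the same event
when both the TE sequence *and* its flanks align — the flanks identify the
locus, while TE-interior similarity alone only identifies the family. The
pipeline operationalizes this as: reciprocal best hit between
flank-extended copies, validated by requiring that the alignment cover at
least a fraction `flank_overlap_min` of the flanking regions. A maximal
clique in the resulting copy graph is taken as one insertion event; a
copy may belong to several maximal cliques when it has diverged
differently with respect to two groups of genomes, and it is then
reported in each.

Assumptions: assemblies are of one species and share chromosome naming
(homonymous-chromosome matching is the default and can be disabled);
annotations are made against a common consensus library and carry the
consensus match span and identity; orthologous flanks remain alignable,
i.e. the loci have not been rearranged beyond what the flank filter
tolerates.

## Parameters

| parameter | default | units | role |
|---|---|---|---|
| `covcons_min`–`covcons_max` | 95–105 | % of consensus | full-length copy window (closed interval; >100% = copy longer than consensus) |
| `flank_bp` | 500 | bp | flank extension on each side, clamped at chromosome ends |
| `flank_overlap_min` | 0.80 | fraction | minimum alignment coverage of each flank (inclusive) |
| `merge_max_gap` | 500 | bp | maximum gap bridged when merging collinear fragments |
| `seed_k` | 15 | bp | exact k-mer seed length of the built-in aligner |
| match/mismatch/open/extend | +2/−3/−5/−2 | score | affine-gap scoring (gap of length L costs open + L·extend) |
| `cloud_max_frac`, `softcore_min_frac` | 0.20, 0.95 | fraction of N | compartment boundaries, applied as floors |
| `calibration_distance`, `calibration_age` | 0.1549, 23 | subst/site, kya | two-point molecular calibration (species-specific) |
| `ancient_distance_threshold` | 0.20 | subst/site | recent/ancient boundary (≈ 30 kya under the default calibration) |
| `conserved_min_fraction` | 37/42 | fraction of N | ancient-and-conserved boundary, applied as a ceiling |
| `recent_max_accessions` | 6 | accessions | maximum sharing size of the recent category |
| `recent_identity_min` | 95 | % | singleton recency proxy (strict inequality) |
| `holocene_age` | 7.5 | kya | post-Holocene recency proxy |

## Design choices where the design was open

- **Best hit** is defined by the merged alignment score; exact ties are
  broken by the (chromosome name, start) of the matched copy, ascending,
  which makes the whole pipeline deterministic and invariant to input
  order.
- **Flank overlap** is applied per flank and per copy (all four coverages
  must reach the threshold). A pooled mode (`combined`: covered flank
  bases / total flank bases) is provided because either reading of an
  "80% overlap of the flanking regions" rule is defensible; per-flank is
  stricter and is the default. An empty flank (copy at a chromosome end)
  counts as covered rather than failing the edge.
- **Compartment boundaries** are floors of the panel fractions
  (⌊0.20·N⌋, ⌊0.95·N⌋). At N = 42 this yields exactly the integer ranges
  2–7 / 8–38 / 39–41 / 42; the floor rule is the simple rule consistent
  with those ranges and scales to other panel sizes.
- **Category precedence** for dated insertions is
  ancient-and-conserved → post-cluster-divergence → recent →
  ancient-not-conserved, with an explicit `unclassified` bucket, because
  the four categories are neither exhaustive nor mutually exclusive as
  ranges (e.g. sharing size 10 with max distance < 0.20 fits none). The
  conserved boundary scales as ⌈(37/42)·N⌉ rather than being the absolute
  count 37, so it transfers to other panel sizes.
- **covcons** is read from the annotation's consensus match span rather
  than recomputed by alignment: the annotation step already provides it,
  and this keeps the pipeline reference-free and fast.
- **Copy-vs-copy alignment** (not copy-vs-whole-genome): the target set of
  each query is the other genome's flank-extended copies. This bounds
  compute and suffices because only annotated copies can enter cliques.
- Alignment scores are symmetric, so alignments are computed once per
  unordered genome pair and both best-hit directions are read from the
  same merged match list.

## Numerical and algorithmic details

The built-in aligner seeds with exact shared k-mers, keeps the longest
strictly-collinear chain (LIS on target positions), and runs a banded
local Gotoh alignment whose band spans the chain's diagonal range plus a
pad (`band_pad`, default 24). The traceback yields the aligned span and
identity over aligned columns. Orientation is chosen by whichever strand
yields the longer chain; minus-strand coordinates are reported on the
forward strand of the target. Pairs sharing fewer than `min_seed_anchors`
(default 4) collinear anchors are not aligned — unrelated sequences
almost never reach this at k = 15, so the null cost is a dictionary
lookup, not a DP. On ≤ 2 kb sequence pairs with ≥ 95% identity the
banded score matches full dynamic programming to within 5% (it is exact
in the test cases; the band only truncates the search space when indels
accumulate faster than the pad).

Degenerate inputs: N bases never match (they break seeds and score as
mismatches in the DP); copies retaining less than half the requested
flank on a side are flagged `short_flank` and kept by default
(`keep_short_flanks=False` drops them); singleton cliques are undated
(dating requires two carriers); a distance matrix must be symmetric with
a zero diagonal and non-negative entries, enforced at construction.

## What the simulator emulates — and what it does not

The simulator plants TE consensus sequences at well-separated loci
(minimum spacing 2·flank + max TE length + 200 bp) on a random ancestral
backbone shared by all accessions, realizes each accession by splicing in
exactly its insertions, and applies independent per-base substitutions to
the whole realized genome, so flank divergence between two accessions is
roughly twice the per-accession rate. Annotation identity is computed
from the actual substitutions in each copy, and all coordinates account
for upstream insertions. Optional modes add random background indels
(which stress the flank filter) and translocations (a copy moved together
with its flanking backbone segment to another chromosome, exercising
relocation flagging).

It does not simulate TE nesting, target-site duplications, LTR internal
structure, excision, large structural variation, or assembly error.
Passing recovery tests therefore demonstrates the correctness of the
matching/clique machinery under point-mutation divergence on a collinear
background — not robustness to fragmented assemblies or rearranged loci,
which real pangenomes contain.

Problem sizes used in the validation suite: the end-to-end recovery check
runs 20 genomes with two 200 kb chromosomes and 50 planted insertions
(sharing sizes uniform on 1..20) at substitution rates 1% and 5%; unit
and property tests use 2–6 genomes with 30–60 kb chromosomes. These sizes
give dense coverage of sharing-set sizes while keeping a full run in tens
of seconds.

## Known limitations

- Maximal-clique counts can exceed the number of true events when
  divergence fractures a clique; near-clique community detection is out
  of scope by design.
- The SNP-distance age is a lower bound and is reported as such; no
  coalescent correction is applied.
- The external-aligner mode consumes PAF files; it does not shell out to
  an aligner itself.
- Homonymous-chromosome matching assumes consistent chromosome naming
  across assemblies; a name-alias map is available in the configuration.
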