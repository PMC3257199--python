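# Methods

## Scientific setting

Domesticated genes are host single-copy genes derived from the coding
sequence of a transposable element (a retroelement *gag*, integrase or
*env* gene, or a DNA transposase).  Vertebrate TE coding regions are
intronless, so the ancestral intron state of a domesticated gene is
known to be zero and every intron it carries is a de novo gain.  This
removes the usual ambiguity of intron gain/loss reconstruction: a
homologous intron site needs exactly one gain, and any patchy presence
below the gain node is explained by losses.  `introgain` implements
that inference — from annotated gene structures to per-ancestor gain
tallies — together with the surrounding descriptive statistics
(positional bias, densities, sizes, sequence conservation, repeat
occupancy) and a simulator that generates data under the same model.

## Coordinates and gene models

All intervals are 0-based half-open internally; GFF3 I/O converts
from/to 1-based closed coordinates, BED12 is consumed natively
(blocks = exons, thickStart/thickEnd = CDS).  Exons and CDS pieces are
stored in transcription order: minus-strand features are reversed at
parse time, so every region-relative quantity (intron ordinal, region
offset, codon phase) is strand-agnostic downstream.  When a file
carries several transcripts per gene, one is chosen deterministically:
longest CDS, then longest summed exon length, then lexicographically
smallest transcript id.

An intron is the gap between two consecutive exons.  Gaps shorter than
4 nt cannot hold donor and acceptor dinucleotides and are dropped as
annotation artifacts, with a warning.  Classification into
5'UTR / CDS / 3'UTR is by the insertion point in transcript
coordinates: an intron is CDS only if at least one coding nucleotide
flanks it on each side; an intron exactly at the start- or stop-codon
boundary belongs to the adjacent UTR.  Transcripts without any
annotated CDS yield the distinct class `noncoding` (classifying them
as 5'UTR would be an unfounded claim about an unannotated gene).
Phase of a CDS intron is the count of coding nucleotides 5' of it,
mod 3.

Intron densities are reported pooled — total introns over total region
kilobases across the gene set — because the surveyed quantity is one
density per gene class; per-gene densities are emitted alongside for
transparency.  Pooling makes the statistic invariant under reordering
or partitioning of the gene list.

## Intron position homology

Two introns in different species are the same site when they occupy
the same position in a region alignment.  CDS introns are projected
through a protein alignment of the coding region (the column of the
residue containing, or immediately preceding, the insertion point)
with codon phase kept as a separate equality requirement; UTR introns
are projected through a nucleotide alignment of the UTR.  Projection
maps through the species' own ungapped index, so a projected position
can never land on a gap in that species' row.

Clustering is exact by default (`slack = 0`): same region, equal
phase, equal column.  A positive slack tolerates intron sliding via
deterministic left-to-right single-linkage merging; it is off by
default because conserved positions are the observed regime.  A
species without an intron at a site is scored *absent* only when its
alignment row covers the projected column with a gap-free flank
(default 10 columns) on each side; otherwise it is *unknown*.  This
mirrors the "incomplete" and "?" calls that low-coverage (~2×)
genome assemblies force in practice, and it is what keeps assembly
gaps from being misread as intron losses.

## Dollo placement

Given a site's three-state presence vector and a rooted species tree
with named internal nodes, the gain node is the MRCA of the present
species, read as a gain on the stem branch leading to that clade
(terminal-only presence reports the leaf).  The minimal loss set under
a single gain is the set of stem branches of the maximal subtrees
beneath the gain node whose informative leaves are all absent.
Unknown states are uninformative in both directions: they never pull
the MRCA rootward and never force a loss — equivalent to pruning the
unknown leaves per site.  Gene origins are placed the same way from
gene-level presence.  This single-gain model is hard-coded; no
likelihood rates are estimated, because the counts involved (tens of
gains, near-zero losses) are far too small to inform a rate model.

The placement is verified against an exhaustive oracle: on a fixed
5-leaf tree, every one of the 3^5 three-state patterns is compared
with a brute-force search over all (gain node, loss-branch subset)
combinations restricted to one gain, with ties broken toward the most
recent gain node.

Literature-style inputs whose per-gene intron counts are ranges
("2–6") propagate as (min, max) pairs into the per-node tallies
rather than being averaged.

## Eligibility of DNA-transposon-derived genes

Genes built by fusing a transposase 3' exon onto a host gene, or by
exon-shuffling only the DNA-binding domain, contain pre-existing host
exons, so their ancestral intron state is not zero and they are
excluded from gain timing.  Only whole-TE domestications pass the
filter.  Retroelement-derived genes are eligible by default — fusion
genes essentially do not arise from retroelements — with a metadata
flag for the rare exception (SCAND3-style fusions).

## Sequence conservation and repeat occupancy

Percent identity of two orthologous intron sequences is computed from
a semi-global (end-free) pairwise alignment: match +1, mismatch −1,
gap open −2, gap extend −1 (configurable), identity = matches /
alignment columns excluding terminal-gap overhangs, ×100.  The
published survey never defines its identity computation, so this
definition is pinned here and recorded in output metadata.  The pair
is ordered canonically before aligning, making the statistic exactly
symmetric even when multiple optimal alignments exist.  Introns at or
above 70% identity (the conserved band observed across placental
superorders) are classified highly conserved.  In pipeline runs the
quadratic alignment cost is bounded by a per-intron length cap
(default 5 kb) and a pair budget; longer introns are summarized by
length only.

Repeat occupancy consumes precomputed annotations (BED or RepeatMasker
`.out`, auto-detected; `.out` coordinates converted from 1-based
closed).  Repeats are clipped to the intron, overlaps are merged
before summing, and per-class subtotals are retained.  RepeatMasker is
never executed: the artifact stays download-free and deterministic.

## Simulator

The simulator draws each family's history forward on the species tree:

- **Birth**: the family appears on the stem of `domestication_node`
  (default Eutheria) and exists in every leaf beneath it.
- **Gains**: a Poisson process along every branch of that subtree at
  `gain_rate` events per branch-length unit (branch lengths in units
  of 100 My), with the stem of `burst_node` scaled by
  `burst_multiplier` (defaults 0.5 and 10: the placental stem
  dominates, as inferred for the real gene set).  Per-branch rate
  overrides allow exact ancestor-targeted scenarios, including gains
  on zero-length branches (the override is then an expected count).
- **Placement**: region from `region_weights`
  (0.55 / 0.40 / 0.05 for 5'UTR / CDS / 3'UTR — the survey's
  qualitative bias made explicit; the exact proportions are config,
  not claims), position uniform within the region with positions kept
  distinct per family, length log-normal (μ = ln 800, σ = 1), spanning
  a few hundred to a few thousand nt with a heavy right tail.
- **Losses**: each existing intron is lost on a branch with
  probability 1 − e^(−loss_rate·ℓ).  The default loss_rate of 0.005
  per branch-length unit means roughly 6% of sites experience any
  loss across the placental subtree — losses rare and taxonomically
  restricted, which is the regime being emulated.
- **Sequences**: exonic regions and intron sequences evolve under
  Jukes–Cantor (default 0.05 substitutions per site per unit) from
  random ancestral sequences.  No indels are simulated, so the
  emitted region alignments are gap-free by construction and homology
  recovery is testable independently of alignment quality.
- **Censoring**: `unknown_rate` removes a species' data for a family,
  emulating incomplete genomes.

Everything is driven by one integer seed through a single
`numpy.random.Generator`; a fixed seed reproduces every output file
byte for byte.  What the simulator deliberately does not model:
splice-site sequence realism, TE insertion mechanics, selection,
intronization of pre-existing exonic sequence, alignment error, or
annotation error beyond censoring.  Passing recovery tests therefore
show that the inference is correct *given* correct annotations and
alignments, not that real annotations are that clean.

## Packaged survey fixtures

The package ships transcriptions of the published survey's tables as
TSVs: the DNA-transposon and retroelement family metadata (TE group,
origin route, intron locations and count ranges), the per-gene origin
node, and the per-superorder intron-position-conservation states.  The
published text states that 36 DNA-transposon-derived genes were
analyzed and 11 used, but enumerates only the intron-containing ones
with two aggregate rows; the packaged 36-row set is reconstructed
mechanically (rule stated in the file's provenance comments) so that
exactly the 11 named whole-TE genes are eligible.  The species tree is
a 17-leaf named-node chordate tree with two representatives per
placental superorder, marsupial and monotreme representatives, and
sauropsid/amphibian/fish/cephalochordate outgroups; the placental root
is left as a Boreoeutheria–Xenarthra–Afrotheria polytomy rather than
committing to one rooting hypothesis.  Branch lengths (units of
100 My) are round figures consistent with conventional divergence
times; only the simulator uses them, never the parsimony placement.

The three-state gene presence matrix is derived, not transcribed:
origin at node N ⇒ present in every sampled leaf under N, absent
outside, with superorders whose conservation cell is
incomplete/undetermined censored to unknown.  A validation test
confirms that the MRCA of every derived pattern reproduces the
transcribed origin node.

## Problem sizes and tolerances

Tests run the simulator at 4–90 families (up to ~600 gain events per
run), the Dollo oracle over all 243 patterns of a 5-leaf tree, and
calibration at 600 replicate families (per-branch empirical means
within 3 standard errors of rate × length; region frequencies tested
by χ² at α = 0.01 on ≥1000 gains).  Floating comparisons use 1e-9 for
the identity symmetry invariant and exact equality for counts.
Degenerate inputs are defined rather than rejected where a sensible
value exists: empty gene lists give all-zero densities, zero/zero
densities warn, single-exon transcripts give no introns; zero region
length with nonzero introns is an error.

## Known limitations

- Origins and tallies from the fixture bundle inherit the published
  tables' granularity: families with unprinted counts (aggregate
  rows) contribute to family counts but not to gain tallies, and the
  published grand totals that cannot be re-derived from the tables
  themselves are not forced.
- The internal fallback when no alignment is supplied is a trust
  downgrade, not a replacement for genomic alignments; conclusions
  about UTR intron homology are only as good as the UTR alignment.
- Dollo placement under losses is conservative by construction: a
  loss that strips a peripheral clade pulls the recovered gain node
  tipward.  The recovery tests quantify this under the documented
  loss rate.
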