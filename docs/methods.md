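# Methods

This note documents the models and procedures the package implements, the
parameters that matter, what the synthetic cohort does and does not
emulate, and the numerical decisions taken where the field's conventions
leave room.

## Pangenome model

Predicted proteins are clustered into orthologous groups (OGs) with a
reciprocal-best-hit (RBH) graph: proteins of two different genomes are
joined iff a local BLOSUM62 alignment (gap open 11, extend 1) reaches
identity ≥ 0.30 (matches / aligned columns, gapped columns included) and
coverage ≥ 0.70 (aligned span on the shorter sequence / its length), and
each protein is the other's best hit in the counterpart genome.  OGs are
the connected components of this graph.  RBH components replace spectral
partitioning deliberately: the downstream statistics depend only on the
identity/coverage thresholds and the core/accessory/unique partition, and
RBH components are deterministic and auditable.  Candidate pairs are
pre-filtered by a shared exact amino-acid 5-mer; at the 30 %/70 %
thresholds on proteins of realistic length this filter is lossless in
practice (a qualifying alignment without a shared 5-mer would need < 1
identity per 20 residues over 70 % of the protein).  Best-hit ties break
by higher identity, then lexicographic gene id, so the partition is
invariant under input order.

Categories follow the usual partition: *core* OGs span all genomes,
*unique* OGs exactly one, the rest are *accessory*.  Accumulation curves
are computed over full random permutations of genome order (default 100;
a permutation-based estimator replaces sampled-subset heuristics because
cohorts at desk scale make full permutations cheap), and openness is read
from a nonlinear least-squares fit of `y = A·x^B + C` (initialised at
`A = y(1), B = 0.5, C = 0`): open iff `0 < B < 1` strictly.  A numerically
constant curve short-circuits to `B = 0` (closed) because the power-law
model is unidentifiable there; non-convergence returns a flagged model
rather than raising.

## Prophage discovery

Candidates are maximal clusters of hallmark virion genes — terminase,
major capsid/head, portal, matched case-insensitively on product strings —
with at least 2 of the 3 classes within 60 kb (hallmark genes more than
30 kb apart start a new cluster).  The 2-of-3 quorum tolerates annotation
gaps while excluding lone integrases; all keyword lists and distances are
arguments.

Boundaries are delineated against a prophage-free reference genome:
20-mers unique in both genomes serve as anchors, the anchors nearest the
candidate on each side fix the local alignment offset, and base-by-base
extension toward the candidate finds the exact break-points.  The
prophage is the maximal lysogen segment absent from the reference that
contains the candidate.  A side with no anchored flank leaves that
terminus at the contig end and marks the region incomplete.  Exact
extension implies the method expects locally identical flanks (the
situation after clonal divergence at desk scale); flanks with SNPs would
shorten the recovered interval — a known limitation, acceptable because
att-site snapping (below) re-derives the final boundaries from the direct
repeat, not from the extension.

att prediction searches 500 bp windows centred on the two boundaries for
the longest common substring ≥ 15 nt occurring exactly once per window
(repeat length and window are arguments; at these defaults a chance
duplicate in a 300 kb genome is vanishingly unlikely).  The region is
then snapped to run from the end of attL to the end of attR, i.e. the
reported region is *interior + one att copy*, with attL immediately
upstream.  This convention makes excision arithmetic exact:
`len(lysogen) = len(restored host) + len(circular phage)` since the
lysogen carries two att copies and each product carries one.  The attB
locus is any tRNA gene of the host whose sequence contains the att core
directly or reverse-complemented.

## Fragmented similarity and clades

The clade statistic tiles the query into 200 bp fragments at 100 bp
stride (queries shorter than one fragment are a single whole-sequence
fragment; only full-length fragments are tiled), scores each fragment
against the whole subject with blastn-style local alignment (match +1,
mismatch −3, gap opening 5 plus 2 per gapped base), normalises by the
fragment self-score, and averages (no fragment-level filtering, i.e.
threshold 0 %).  The published tool's normalisation is not public as a
formula; mean best-fragment normalised score reproduces the qualitative
block structure the clade thresholds act on, and the thresholds are
arguments for users who calibrate differently.  The empirical null for
unrelated random 10 kb sequences sits near 5 % (chance micro-alignments),
far below any threshold in use.

For long subjects the fragment alignment is seeded: exact 12-mers vote
for 32-column diagonal bands, and Smith–Waterman (Biopython's C
`PairwiseAligner`) runs only on the padded top bands; a fragment with no
seed scores 0.  For small problems the exact DP runs directly, and the
seeded path is tested against it.

Clades are single-linkage components over pairs whose symmetrised (mean
of both directions) similarity exceeds 60, numbered by descending size
then first appearance; between-clade pairs above 40 are reported as
relations without merging.  Single linkage matches the definition of
clade cohesion as a pairwise whole-sequence identity criterion.

## CRISPR arrays and protospacer matching

Array detection is CRT-style: two exact seed-sharing repeat copies
(16-mer seed) at a spacer-compatible period nucleate a candidate; the
repeat is maximised by exact extension, the array is grown greedily in
both directions allowing one mismatch per additional copy, and the repeat
boundaries are then refined across *all* copies — a boundary column that
is not unanimous is flanking sequence dragged in by a coincidental
two-copy agreement and is trimmed.  Repeats are accepted at 23–47 nt,
spacers at 26–50 nt, minimum three copies.

Spacer-to-prophage matching is a full-length ungapped alignment on either
strand with two filters, both required: at most 3 mismatches, and an
ungapped blastn bit score ≥ 44.1, computed as `(λ·S − ln K)/ln 2` with
λ = 1.374 and K = 0.711 (the published ungapped constants for the +1/−3
system) and raw score `S = len − 4·m`.  At the median 34-nt spacer length
three mismatches give S = 22 and 44.1 bits exactly, which is why the
cutoff is interpreted this way; gapped matching is out of scope because
blastn-short on 26–50-mers with ≤ 3 edits essentially never gaps.
Candidates come from pigeonhole seeding — the query is split into
`max_mismatches + 1` chunks, one of which must match exactly — so the hit
set is provably identical to a naive all-positions Hamming scan (a plain
11-mer seed would not be: 3 mismatches can break every 11-run of a 34-mer).
`N` never counts as a match anywhere.

The PAM is defined as the 3 nt immediately 5′ of the protospacer read on
the protospacer's strand, compared with TCC; a protospacer flush with the
sequence edge is reported PAM-negative with an edge flag.  Targeting
matrices count distinct spacers per (host, clade); PAM status is reported
but never gates the counts, and self-targeting (a host's spacer hitting a
prophage resident in the same host) is flagged with its PAM status.

## DGR and shufflon detection

Repeat pairs are found per copy-offset: exact 20-mer recurrences propose
offsets, the per-offset match profile is scanned for the best window of
length 100–150 with Hamming identity ≥ 0.90, scored match +1 / mismatch −3
(flanking junk at ~25 % chance agreement is firmly negative in
expectation) with ties broken toward the shorter window — the minimal
maximal-scoring segment, so zero-sum tails are never absorbed.  The same
scan run over all offsets is the exhaustive oracle used in tests.
Identity is computed over the selected aligned window (the repeats are
treated as ungapped copies).

A DGR requires a reverse-transcriptase gene (product keywords); of a
qualifying repeat pair, the member nearer to — or inside — the RT gene is
the template repeat (TR) and the other the variable repeat (VR), which
must lie inside a gene (the *mtd* candidate).  A small gene (≤ 600 nt)
between TR and mtd is reported as the *avd* candidate.  The architecture
is `TR_within_ert` when the TR is nested in the RT gene and
`TR_upstream_of_ert` otherwise.  Variable sites across isolates are the
VR columns (anchored to the TR, equal lengths required) showing ≥ 2
distinct bases among the TR and the isolate VRs; the variant space of
*n* sites is `4^n` (each site can carry any base — 10 sites give
1,048,576 ≈ 10^6 variants, which is what fixes the per-site alphabet
at 4 rather than 3).

The rix scanner reports every exact occurrence of the 8-mer motif
(direct) and of its reverse complement (inverted), case-insensitive,
overlaps allowed; degenerate matching is deliberately off by default.  A
shufflon requires an invertase-like gene distinct from the integrase; Rv
cassettes are the intervals between consecutive direct rix sites
downstream of it (gaps ≤ 1 kb), and the Rc gene is the first large gene
(≥ 600 nt) after the last cassette with an inverted rix within 200 nt of
its stop.  Rv↔Rc homology is reported as the best ungapped-offset
identity against the Rc C-terminal 120 nt rather than local-alignment
identity: local alignment trims to short exact runs and saturates near
1.0 regardless of overall divergence, whereas the sliding ungapped
measure reports ~0.70 for a 30 %-diverged copy and stays near the 0.25
background for unrelated sequences.

## Activity evidence

The coverage ratio is mean depth inside the prophage over mean depth
outside, with every prophage interval excluded from the host background
(so one induced prophage does not deflate the contrast for another;
inclusion is a toggle).  Mean is the default because the upstream
quantity of interest is average coverage; median is available.  A zero
host background yields NaN (flagged), and the statistic is invariant
under rescaling the whole profile.  Excision verifies the attL/attR
geometry, restores the host with one att copy and circularises the
prophage with the other; the reported attP junction is 100 nt centred on
the att core across the circle's origin — the sequence a
junction-spanning amplicon would read.  In-silico PCR uses exact primer
matching (≥ 15 nt), convergent orientation, products capped at 3 kb, and
searches circular templates across the origin; junction-flanking outward
primers amplify from the excised circle only, which is the discriminating
assay for excision.

## The synthetic cohort

`SimulationConfig` defaults define the study conditions: 10 genomes of
~300 kb at GC 0.635; prophages of 32–42 kb at GC 0.58–0.67 integrating at
tRNA-Leu/Ser/Arg/Ala loci whose 3′ ends carry 42–45 nt att cores (the
clade-1 core is a real 43-nt attP sequence); four clades sized (3,2,2,2)
— a shufflon clade, a TR-embedded DGR clade, and two TR-upstream DGR
clades of which the fourth is derived from the third at 10 % divergence
(the planted "related pair", landing near 52 % fragmented identity:
above the 40 % reporting threshold, below the 60 % clade threshold);
within-clade member divergence 1.5 % per base (pairwise ~3 %, fragmented
identity ~88 %); TR length 130 (123 when embedded) with 10 variable
sites; 3 Rv cassettes with the ttccgtat rix motif; 34-nt spacers on a
29-nt repeat with planted mismatch counts 0–3 plus one at 4 (beyond the
matching rule), PAMs on a subset, one self-targeting spacer, and two
random decoys per array; Poisson depth at base 50 with induction factors
drawn from 1.1–5.2.  The 300 kb genome length is a scaled-down stand-in
for multi-megabase chromosomes chosen so that full-pipeline runs take
seconds; every detection threshold downstream is length-independent.
The within-clade divergence is a calibration of this generator (chosen so
within-clade identity clears 60 % comfortably), not an empirical value.

Planted truth is guaranteed recoverable by construction: background
sequence is rejection-scrubbed so the rix motif, the CRISPR repeat and
the att cores occur only where planted; the columns flanking att cores
and TR/VR copies are forced to disagree so the planted repeat is the
unique maximal one; and member mutation spares protected intervals
(rix sites, TR/VR ± 2, the interior's terminal bases).  Genes are planted
as stop-free ORFs with synthetic product strings, because real annotation
pipelines are out of scope and hallmark screening keys on product text.

What the generator does **not** emulate — and what passing tests
therefore do not certify on real data: SNP divergence of the shared host
backbone (delineation flanks are exact here; real strains add SNPs and
rearrangements), indels within prophage clades (members differ by
substitutions only), sequencing error or assembly fragmentation beyond
simple contig-end truncation, annotation noise in product strings, and
degenerate rix or att motifs.

## Problem sizes and determinism

Default test/acceptance runs use the 10-genome, ~330 kb-lysogen cohort
(nine prophages, three arrays, 14 spacers), the full 9×9 fragmented
similarity matrix, and small (≤ 5 kb) sequences wherever a quadratic
brute-force oracle certifies an optimised path.  Everything is seeded:
the generator requires an explicit seed and is byte-deterministic under
it; permutation and noise steps take NumPy `Generator` objects or integer
seeds.

## Known limitations

* Boundary delineation assumes an alignable, locally identical flank in
  the reference; diverged flanks degrade precision (att snapping
  recovers it only where an att repeat exists).
* Fragmented similarity with seeded banding can miss weak, gappy
  homology a full DP would find; at the 40/60 thresholds in use this has
  no effect, but the statistic should not be read as a sensitive
  homology search.
* Repeat-window selection can, with small probability, extend a true
  repeat across a flanking mismatch if several chance agreements follow;
  the generator's two-column guards make planted recovery exact, but on
  real data reported TR/VR termini are approximate by a few bases.
* Gene identification is keyword-based by design; profile-HMM detection
  of RT/invertase genes is out of scope.
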