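# Methods

This note documents the models, conventions and numerical choices behind
`pancomp`, in the order the pipeline runs them, together with what the
synthetic-data generator does and does not emulate.

## Intergenomic similarity

The taxonomic scalar for a genome pair is

    S(a, b) = 100 x mean(coverage_a, coverage_b) x identity

where `coverage_x` is the fraction of genome *x* inside aligned blocks and
`identity` is the aligned-column-weighted match fraction across all blocks
(gap columns count as mismatching). Coverage is symmetrized as the mean of
the two one-sided coverages so that S(a,b) = S(b,a); directional top-hit
coverage would make the score depend on query order, which a partition
built from S cannot tolerate. Values are carried at full precision and
rounded half-up to one decimal only for display.

### The chained aligner

`align_pair` is a desk-scale stand-in for a nucleotide homology search:

1. **Seeding.** Exact k-mer anchors (default k = 13, both strands of the
   subject); k-mers containing N are skipped, and k-mers occurring more
   than 10 times in the subject are treated as repeats and ignored.
2. **Diagonal runs.** Seed hits are merged into maximal exact runs per
   diagonal; runs on one diagonal separated by substitution stretches are
   joined, with the intervening columns scored by direct comparison (or
   realigned when that looks poor -- balanced indels can hide inside an
   equal-length gap).
3. **Chaining.** A collinear dynamic program over anchors maximizes the
   canonical alignment score (match +1, mismatch -1, gap -1), with a
   transition penalty of the net diagonal shift plus an expected-mismatch
   term, small anchor overlaps tolerated and trimmed, and terminal anchors
   dropped when their connection cost exceeds their score (mirroring how a
   free-end-gap DP would trim them).
4. **Gap fill and block breaks.** Gaps between chained anchors whose
   lengths differ by at most `indel_break` (100 bp) are filled by exact DP
   (edit distance via `edlib` for segments above `nw_fill_limit` = 600 bp);
   larger one-sided gaps are *unaligned insertions* -- the block is split,
   so whole-gene gain/loss reduces coverage instead of diluting identity.
5. **End extension.** Chain ends extend by a pinned-start/free-end DP over
   at most `extension_cap` (250 bp) per side.
6. **Polish.** Any block whose window area is below `polish_cells`
   (6 x 10^6 cells, roughly 2.4 kb x 2.4 kb) is re-aligned exactly by the
   canonical free-end-gap DP, with extra window margin at chain ends so
   weak terminal regions beyond the outermost anchors are placed the same
   way a whole-sequence DP would place them. Genome-scale blocks keep the
   chain-and-fill result.

The polish step makes the aligner effectively exact on gene-scale problems
(agreement with a full-DP oracle to < 0.01 identity on random pairs up to
2 kb) while staying O(anchors^2 + fills) on full phage genomes.

### One canonical DP convention

Every residue-level alignment in the package (protein identity, gap fills,
polish, the test oracles) uses one convention: match +1, mismatch -1, gap
-1, free end gaps on both sequences, best end cell chosen by score then
alignment length then row, traceback preferring diagonal, then up, then
left. Fixing the tie-breaks makes match counts and spans well defined, so
independent reimplementations agree *exactly*; this is why the module
carries its own DP instead of delegating to a library aligner whose
tie-breaking is unspecified.

### Dereplication

Greedy and longest-first: a genome is redundant iff identity >= 95% *and*
mean coverage >= 80% against an already-kept representative. Requiring
both mirrors the clustering tools used for building nonredundant phage
sets (minimum sequence identity 0.95, coverage 0.8).

## Taxonomy

Pairs at S >= 95 are one species; 70 <= S < 95 one genus, distinct
species; S < 70 distinct genera. Whole-collection partitions are
single-linkage connected components at each threshold -- the only linkage
under which the pairwise statements and the partition are always mutually
consistent -- with cluster labels taken from the lexicographically
smallest member. Species components are computed at the higher threshold,
so the species partition refines the genus partition by construction.

Trees are neighbour joining (scikit-bio) on (100 - S)/100 distances, or on
p-distances from concatenated marker alignments; negative NJ branch
lengths are clamped to zero. Monophyly on an unrooted tree is the *clan*
test: a tip set passes iff some single edge separates it from all other
tips (equivalently, it is a clade under some rooting).

A family proposal over a candidate genome set is evaluated on three
criteria: (a) its soft-core is at least `min_core_pct` (default 10%) of
the mean proteome -- the default is taken from the observed core share of
a family proposed at about ten percent shared orthologues, and is a
configuration knob, not a community-standard constant; (b) the candidates
form a clan of the supplied tree; (c) no soft-core clusters are shared
with any neighbouring family on a joint clustering.

Marker-hit selection keeps rows with e-value strictly below 1e-3 and the
minimum-e-value row per (genome, marker), ties broken by gene id.

## Consensus ORF calling

Predictor calls are merged by (genome, strand, stop coordinate) -- callers
disagree on start codons far more often than on stops -- keeping the
most-upstream start and the set of supporting callers. Six one-point
criteria score each candidate; the thresholds operationalize criteria that
are named but not numerically specified in the annotation literature this
scoring scheme descends from, and all are exposed in `ConsensusConfig`:

| criterion | default operationalization |
|---|---|
| caller support | called by >= half the predictors |
| length | >= 120 bp |
| overlap | <= 30 bp overlap with any better-supported candidate |
| homology | table hit at e < 1e-3 on the same strand |
| coding potential | in-frame hexamer log-odds > 0 (undefined < 60 bp) |
| operon context | same-strand neighbour with intergenic gap <= 50 bp |

Score >= 3 keeps a gene; score <= 2 is rescued only by a homology hit or
>= 2 supporting callers, else dropped. Whether the original scheme weights
its criteria is not determinable from its description; the unweighted
count is used here and flagged as an interpretation. The hexamer
background is trained per genome on its own majority-supported candidates
(add-one smoothing over 4096 in-frame hexamers, log-odds against uniform),
so no external model files are needed; a model trained on uniform-random
sequence scores fresh random sequence at ~0 by construction.

## Pangenome and soft core

Proteins are clustered greedily, longest first (ties by gene id), each
protein joining the earliest-founded centroid it matches at >= 30%
identity with >= 80% coverage *of both sequences* (bidirectional coverage
is the named clustering tool's default coverage mode; the flag itself does
not say). A length-ratio and shared-4-mer prescreen skips alignments that
cannot reach the thresholds. In the well-separated regime (within-cluster
identity far above, between-cluster far below the threshold) the greedy
partition coincides with single-linkage clustering, which the tests assert.

The soft-core of a genome set is the clusters present in strictly more
than 95% of its genomes. Strict ">" follows the defining wording "found in
>95%"; an "at least 95%" reading also circulates, so the comparison
operator and fraction are configuration options. Core share is reported as
core count / mean proteome size x 100.

## AMG curation and statistics

A DRAM-v-style annotation row survives curation iff rank is A, B or C
('C or higher', with A the most confident), flags contain 'M' (metabolic),
and none of V, B, T is present. Rank 'B' and flag 'B' are distinct symbols
from distinct columns. The 'F' flag (gene at a genome end) never causes
removal -- it marks a prophage-boundary concern that does not apply to
complete genomes -- and unknown flags pass through without effect. Codon
usage excludes each gene's terminal stop codon by default (config-exposed),
and usage differences are phage-minus-host frequency vectors, which sum to
zero by construction.

Association statistics are ordinary least squares (slope, intercept, R^2,
slope F-test p, which equals the two-sided slope t-test in simple
regression) and the unpaired pooled-variance t-test; a degenerate
zero-variance equal-mean comparison returns t = 0, p = 1.

## The synthetic generator

A genome is an ordered series of gene slots (random codon sequences with
intact start/stop codons and no in-frame stops, ~900 bp by default, 30%
on the minus strand) separated by 20-200 bp spacers, including a shared
trailing spacer. Each family owns core slots (present everywhere),
family-wide flexible slots, and genus-specific flexible slots, in one
global order so genomes stay collinear. Each species drops a fixed number
of flexible slots -- a sliding window over a per-genus shuffled pool, so
drops tile the pool deterministically and, when `species x drops >= pool`,
every flexible cluster is absent somewhere (making realized soft-core
equal designed core). Genomes of one species have identical content.

Divergence tiers are *targets on the S scale*, reached by two multiplying
factors: gene-content overlap sets coverage, per-site substitutions along
the family -> genus -> species -> genome lineage set identity on shared
sequence. Pairwise identity relates to the per-lineage substitution
probability p by I = (1-p)^2 + p^2/3 (independent lineages, substitutions
uniform over the other three bases), which is inverted in closed form;
branch rates are then solved level by level against the *realized*,
bp-weighted content-overlap fractions of the generated presence sets.
Substitutions never create in-frame stops and spare start/stop codons.
With the default tiers (0.98 / 0.80 / 0.40) the realized per-tier mean S
lands within +/-3 points of target at the 40 kb scale, and individual
pairs stay on the correct side of the 95/70 thresholds by >= 2 points at
the 10 kb test scale.

Predictor calls detect each true gene per caller with probability
`predictor_sensitivity`, jitter the called start downstream by a multiple
of 3 with probability 0.15, and add Poisson false ORFs per genome, each
supported by a single caller. AMG truth plants per-genome AMG counts as
Poisson with mean `amg_rate_per_kb x genome_kb`, so the count-vs-size
regression has a recoverable slope equal to the rate; the annotation table
adds distractor rows of the three kinds the curation rule must reject.

What the generator does **not** emulate: synteny rearrangements and
recombination (genomes are collinear by construction, so the aligner's
chaining is never stressed by translocations), within-gene indels (indels
exist only as whole-gene gain/loss), GC and codon-usage structure (bases
are uniform, so codon-bias analyses on synthetic data are null by
construction), tRNA/intron sequence realism, and sequencing error.
Passing tests therefore certify the analysis logic on idealized colinear
genomes, not robustness to misassembly or rearrangement.

## Problem sizes and seeds

Tests and the acceptance script run at desk scale, chosen so the full
battery completes in minutes on one core: 10 kb genomes with ~600 bp genes
for taxonomy-recovery collections (24 genomes, 20 seeds in the test suite,
5 seeds in the script), the 41 kb / 58-gene configuration for the
17-genome soft-core family, 200 random pairs up to 2 kb for the
aligner-vs-DP comparison, 10,000 replicates for t-test calibration and 100
seeds (n = 200 each) for slope recovery. All randomness flows from
`numpy.random.SeedSequence` with explicit integer keys, so every result is
bit-reproducible given (config, seed) and independent of insertion order.

## Known limitations

* The chained aligner assumes collinearity; a true inversion would be
  recovered only as a separate minus-strand block, and duplicated regions
  are aligned once (query-side masking).
* Greedy centroid clustering matches single linkage only in the
  well-separated regime; near the 30% identity threshold the two can
  legitimately differ, as they do for the tools they mirror.
* The 2-SE slope-recovery check has ~95% per-seed success probability by
  construction, so its >= 95/100 pass mark is intrinsically tight; the
  fixed-seed design makes the reported value reproducible.
* Statistical helpers are deliberately thin wrappers over scipy and do not
  attempt robust or nonparametric alternatives.
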