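# Methods

`crisprpop` analyzes viral-resistance diversity encoded in CRISPR spacer
arrays against housekeeping-gene (MLSA) diversity within a single microbial
population, and ships a forward simulator that generates ground-truthed
inputs for every stage. This note describes the models and procedures, the
parameters that matter, and the design choices made where the design was
genuinely open.

## Spacer extraction (`arrays`)

A CRISPR locus is parsed by locating copies of its direct repeat — the
built-in definitions are the two *Sulfolobus islandicus* families,
`GATAATCTACTATAGAATTGAAAG` (A family, 24 nt, used by the A1 and A2 loci) and
`GATTAATCCTAAAAGGAATTGAAAG` (C family, 25 nt) — and emitting the substrings
strictly between consecutive copies as spacers, numbered 1..n from the
leader-most spacer of the sequenced fragment.

* Repeat search is an exhaustive per-offset Hamming scan on both strands
  (amplicons are a few kb, so no indexing is needed). Overlapping candidates
  are resolved greedily left to right, preferring fewer mismatches: repeats
  never legitimately overlap in a real locus.
* `max_mismatches` defaults to 2 for FASTA loading. Exact matching (0) is
  the literal laboratory procedure; tolerance is useful because loci in
  divergent strains fail to amplify or accumulate repeat variants. Records
  whose repeats cannot be found are reported with status `NA`; records
  flagged in their header with a trailing `|X` are loci known to be absent.
* Orientation: if the repeat copies are found on the minus strand, the
  record is reverse-complemented before extraction, so arrays are always
  leader-to-trailer. Strand choice is by majority when mixed-strand hits
  occur (which indicates a dubious record).
* Zero-length gaps between abutting repeats are sequencing artifacts and are
  skipped with a warning rather than emitted.
* Coordinates are 0-based half-open internally; emitted spacer positions are
  1-based.

## Spacer identity and similarity (`catalog`)

Two separate equivalence notions drive everything downstream:

* **Exact classes** — full-length identical sequences. These are the
  symbols used for array alignment and ancestry, matching the practice of
  finding 100% spacer matches before judging shared context.
* **Fuzzy matches** — the assembly-style rule: two spacers match when some
  ungapped overlap of ≥ 17 nt reaches ≥ 88% identity. On a full 39-nt
  overlap this admits at most 4 mismatches. Matching is ungapped because
  observed non-identical spacer pairs are offsets and substitutions, not
  indels; reverse-complement matching is off by default for spacer–spacer
  comparison (arrays are orientation-normalized at extraction) and on for
  protospacer search.

`is_match` is defined existentially: true iff *some* offset satisfies both
thresholds. The reported alignment is the best qualifying offset by
(identity, overlap, smaller |offset|, same orientation). Without the
existential form, a 1-nt perfect terminal overlap could outrank a 30-nt
90%-identity overlap and misreport the decision.

Unique-spacer counting uses single-linkage clusters over fuzzy matches,
mirroring contig-assembly semantics (a chain of pairwise overlaps assembles
into one contig); complete linkage is available via `linkage="complete"`.
Both the exact-class count and the cluster count are reported, since
"unique spacers" can reasonably mean either.

Protospacer search is an exhaustive full-length ungapped scan of each
spacer against both strands of every target, scored match +1 / mismatch −1;
100%-identity full-length hits are flagged. An optional gapped mode
(Biopython local alignment, gap −4) handles targets with indels.
`pam_context` extracts k nt of strand-aware flanking sequence (default
k = 2: the protospacer-associated motif in *Sulfolobus* is a dinucleotide);
it performs no motif calling.

## Array comparison (`compare`)

**Alignment.** Arrays are globally aligned over exact-class symbols by
dynamic programming with match +2 and gap −1. Mismatch columns are
disallowed by default — the evolutionary model of array change is leader
acquisition plus internal deletion, not in-place substitution — so
differing spacers force paired gaps. Traceback tie-breaking is fixed
(diagonal, then gap in the first array, then gap in the second), giving a
unique deterministic optimum. Arrays must share locus and end; a fully
sequenced array (`full`) is comparable with either end fragment, otherwise
fully sequenced strains could never be grouped with end-sequenced ones.

**Loss.** A maximal gap run in one row flanked on both sides by match
columns is a loss event with that run length. Terminal gap runs are never
losses: at a fragment boundary, absence of data is indistinguishable from a
shorter amplicon.

**Ancestry.** Strains are grouped per locus by single linkage: two strains
are linked when some shared-end alignment contains ≥ `min_run` identical
spacers in a row (gap columns permitted between them), or ≥ 2 identical
spacers around an internally flanked gap — the loss signature itself is
shared-context evidence, which rescues heavily eroded arrays whose only
remnant is a trailer block interrupted by deletions. `min_run` defaults to
3: a bare pair of adjacent identical spacers between otherwise unrelated
strains is deliberately *not* ancestry evidence, because the acquisition
analysis must be able to set such pairs aside (below) without having merged
the strains first. Pairs linked only by trailer-end evidence are flagged —
the very first conserved trailer spacers can be the sole remnant of deep
shared ancestry.

**Leader-internal check.** If leader-end variability were produced by
spacer loss rather than new acquisition, leader spacers of one strain would
reappear internally (beyond the leader run) in another strain's fully
sequenced locus, in a different context. Each leader-fragment spacer is
searched by exact class against positions > `leader_depth` (default 10) of
other strains' full arrays. Two refinements keep the check meaningful:
matches that sit in a match column of the two arrays' alignment with
further shared context around them are ordinary common ancestry observed at
different leader depths, not leader erosion, and are not reported; and a
fragment's terminal spacer is never used as a query, since for arrays
shorter than the sequencing depth it is the locus's conserved trailer-most
spacer.

**Acquisition classification.** Every cross-strain fuzzy match pair is
classified exactly once:

1. *Ancestral* (discarded): 100% full-length identical pair between strains
   of the same ancestral group at that locus. Adjudication is group-based
   rather than per match column so that a spacer visible only in the leader
   fragment of one strain and only in the trailer fragment of the other is
   still recognized as shared.
2. *Excluded* (returned, flagged): an exact pair with an adjacent exact
   pair (consecutive positions in both arrays, same order) — consecutive
   exact sharing between two strains is almost certainly descent of that
   block even when whole-array ancestry is not supported; and pairs whose
   two classes co-occur within a single strain's genome ("intra-genome") —
   two matching spacers carried side by side, e.g. overlapping windows of
   one virus, are inherited as a unit, so their cross-strain recurrence is
   not evidence of independent acquisition. A single isolated exact pair in
   different contexts remains a live candidate.
3. *Acquisition pair*: everything else — annotated with its match geometry
   (offset, SNP count, length difference) and the sequenced ends of both
   partners (leader–leader / trailer–trailer / mixed; spacers of full
   arrays classify by position ≤ `leader_depth`).

Pairs are de-duplicated so that ancestrally identical copies of a spacer
across the strains of one group count once.

## MLSA genotyping (`mlsa`)

Loci are consumed pre-aligned with equal lengths (MLSA amplicons are
fixed-length coding fragments; alignment is routine and out of scope).
Alleles at a locus are groups of identical sequences; allele 1 is the most
frequent (ties: lexicographically smallest sequence), the rest numbered by
decreasing frequency. By default N matches any base, so single-read
ambiguity does not split alleles; since that relation is not transitive,
sequences are merged greedily into the most frequent compatible existing
allele, iterating exact-sequence groups by (size desc, sequence lex) —
deterministic and permutation-invariant. Allele numbers are arbitrary
labels. Genotypes are ordered allele vectors; SNP counts against a
configurable reference strain are computed on the concatenation with N and
gap columns skipped. `epidemic_summary` reports the size-ranked genotype
table and the dominant genotype's share — the statistic of an epidemic
population structure, where one clonal genotype coexists with rare
recombinant ones.

## Diversity (`diversity`)

* MLSA distance: pairwise p-distance with pairwise deletion of N/gap
  columns.
* CRISPR distance: arrays are coded into a strains × columns categorical
  matrix (one column per locus/end/position; identical spacers in a column
  share a code). Fully sequenced arrays are clipped into leader and trailer
  views so all strains share a column space. Distance is the fraction of
  differing comparable columns; a sequenced-but-absent position (short
  array) counts as a difference, whereas missing data is deleted pairwise.
  Coding is positional per fragment rather than re-aligned across all
  strains; this under-counts similarity when arrays are shifted by leader
  acquisitions, which makes the CRISPR distances conservative (an
  acceptable bias for demonstrating undersampled CRISPR diversity, and the
  price of avoiding a multi-array alignment, which pairwise alignments plus
  transitive coloring otherwise replace).
* OTUs: furthest-neighbor (complete-linkage) clustering at a distance
  cutoff, the classical OTU-binning convention; single/average linkage are
  exposed. Cutoff 0 groups identical individuals.
* Rarefaction: the analytic individual-based (hypergeometric) expectation
  E[S_n] = S − Σᵢ C(N−Nᵢ, n)/C(N, n); Monte-Carlo subsampling is retained
  as a test oracle only.
* Chao1: the bias-corrected form S_obs + F1(F1−1)/(2(F2+1)), which is
  finite when doubletons are absent; the classical F1²/(2F2) value is
  reported alongside when defined.

## Forward simulator (`simulate`)

The generator produces leader/trailer amplicon-end FASTA per CRISPR locus
(headers `{strain}|{locus}|{end}`), a circulating-virus FASTA, per-locus
MLSA FASTA and a complete ground-truth event log. Replaying the log from
the founder states reproduces every strain byte-for-byte.

Structure: a population grows from `n_founders` (default 3) founder
lineages to `n_strains` (default 39) by binary splitting spread evenly over
`n_steps` (default 12) discrete steps. All founders share one MLSA root —
so housekeeping genotypes form one clonal complex — but carry unrelated
CRISPR root arrays, the regime in which a dominant housekeeping genotype
conceals several independent resistance histories.

Per step, per lineage and locus:

* **Acquisition** (rate 0.35): a new spacer is copied from a window of a
  random circulating virus immediately downstream of a PAM dinucleotide
  (default `CC`; the PAM stays on the virus, outside the spacer) and
  inserted at the leader end. Spacer lengths are uniform on 37–41 nt
  (mean 39).
* **Loss** (rate 0.06): a contiguous internal run is deleted; run lengths
  follow a geometric law truncated at 5 with mean exactly 2 (the truncated
  success probability is solved numerically). Terminal spacers are never
  deleted, so the trailer-most root spacer survives in every strain.
* **Locus loss** (probability 0.004): the locus disappears; it is emitted
  as an `|X` record.

MLSA sequences (12 loci × 557 bp = 6684 bp) evolve by point mutation
(10⁻⁵ per site per step, ≈ 0.8 expected substitutions per terminal lineage,
which yields a dominant genotype near half the sample) and by gene
conversion (probability 0.01 per step) copying a 500-nt tract from a
coexisting lineage — the source of rare recombinant genotypes. The
recombination-to-mutation balance is a descriptive input, not an estimated
quantity; conversion events record how many sites they changed.

Founder root arrays (13 spacers per locus) are drawn PAM-adjacent from a
separate *ancient* virus pool no longer in circulation: old spacers target
elements that have left the community. This has three consequences that
mirror real arrays: trailer-end spacers also produce cross-founder
independent-acquisition matches (old acquisitions of shared ancient
viruses), recent and ancestral spacers can never collide exactly, and root
arrays sample protospacer sites without replacement because real arrays
essentially never carry the same spacer twice.

Emission clips each array to the leader-most and trailer-most `end_depth`
(default 10) spacers; `n_full` strains (default 2) are emitted as fully
sequenced loci instead, emulating reference genomes. A random 20% of
fragments are written on the minus strand to exercise orientation handling.
Fragments are repeat-interleaved with 25-nt random flanks.

What the generator does **not** emulate: sequencing error and chimeras,
repeat divergence within a locus, virus evolution and population dynamics,
fitness or selection, insertion of spacers anywhere but the leader, and
calibrated branch lengths (the splitting process is a scheduling device,
not a coalescent). Tests passing on this generator therefore demonstrate
the pipeline's bookkeeping and inference logic under the modeled population
regime, not robustness to raw sequencing artifacts.

## Recovery metrics (`summary_stats`)

Scoring analysis output against ground truth:

* **Losses**: a planted event is *recoverable* when some strain carrying
  the deletion shows both flanking spacers adjacent in an emitted fragment
  while another strain shows the flanks plus the intact lost run; recovery
  demands a detected event with the same strain, locus, flank sequences and
  exact run length. Conditioning on recoverability avoids conflating two
  adjacent planted deletions merged into one observed gap with a violation
  of the run-length law. Detection mildly under-represents long runs (a
  witness must fit run + 2 consecutive spacers inside a sequenced
  fragment), so the run-length law is asserted on planted events and the
  detected runs are checked for support and exact per-event agreement.
* **Ancestry**: pair-counting Rand index between detected groups and the
  founder partition, per locus.
* **Acquisitions**: truth pairs are pairs of distinct acquisition events
  from the same virus whose spacers satisfy the match rule, are sequenced
  in different strains, and were acquired by different lineages (two events
  on one lineage path — evidenced by a strain carrying both — are
  sequential acquisitions by one host). Precision counts detected pairs
  whose two spacers trace to one planted event (inherited copies) as false;
  recall is the fraction of truth pairs recovered.

## Default test and script scale

The test suite and `scripts/acceptance.py` run the simulator at its full
default scale (39 strains, 3 loci, ~2000 sequenced spacers); a complete
simulate–extract–analyze–score cycle takes about one second, and the
20-seed recovery suite runs in ~20 s.

## Known limitations

* Positional (non-realigned) coding for the CRISPR distance matrix, as
  discussed above.
* The intra-genome exclusion is conservative: a strain that sequentially
  acquired two overlapping windows of one virus suppresses the
  corresponding cross-strain pairs even when an independent acquisition
  also occurred elsewhere.
* `pair_match` is O(length²) per pair; the vectorized `match_matrix` keeps
  cataloging fast up to a few thousand unique spacers but no seed indexing
  is attempted (targets and spacer sets here are small).
* MLSA alignment itself (e.g. for unequal-length inputs) is out of scope;
  inputs must be pre-aligned.
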