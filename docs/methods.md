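# Methods

## Model and procedure

seedclust clusters long transcriptomic reads by region of common genomic
origin (gene family), using shared minimizer seeds as the similarity
signal. The pipeline has four stages, all single-threaded and fully
deterministic for a given input and configuration:

1. **Seeding.** For every read, canonical (k, w)-minimizers are computed:
   a window is w consecutive k-mer start positions (half-open, 0-based);
   per position the candidate value is the smaller, under the hash
   ordering, of the k-mer's hash and its reverse complement's hash; the
   window emits the position with the smallest value, leftmost on ties,
   and a position selected by several overlapping windows is reported
   once. Reads shorter than k yield no seeds; reads with fewer than w
   k-mer positions are treated as a single window. k-mers containing
   non-ACGT characters are excluded from candidacy, and a window with no
   valid k-mer emits nothing. Each seed carries a confidence
   P = ∏ (1 − 10^(−q/10)) over its k forward-strand base qualities; seeds
   with P > T1 (strict) are high-confidence seeds (HCS).
2. **Sorting.** Reads are ordered by decreasing HCS count (counting seed
   positions, not distinct values), with a stable sort so ties keep input
   order. The sorted stream can optionally be spilled to a FASTQ file and
   re-streamed.
3. **Greedy clustering.** The first read founds a cluster whose
   representation is its HCS value set. Each later read collects, via an
   inverted seed→cluster index, the number of its distinct seed values
   present in each candidate cluster's representation. Let D be the
   read's number of distinct seed values (all seeds, not only HCS). The
   read joins the best-sharing cluster if shared/D ≥ T2 (ties on the
   shared count go to the oldest cluster id); its HCS not yet in the
   representation are added and indexed. Otherwise it founds a new
   cluster. Reads with no seeds found their own zero-seed cluster with an
   empty representation, which can never attract members.
4. **Merging** (optional). Clusters are visited in ascending
   representation size |HCS| (ties: ascending id). A cluster c1 may merge
   into the cluster c2 maximising |HCS(c1) ∩ HCS(c2)| among targets with
   strictly larger |HCS| — or equal |HCS| and smaller id, so identical
   twins are still mergeable — when the overlap exceeds T3·|HCS(c1)|
   (strict). All decisions in a sweep are evaluated against the
   sweep-start state; a decided merge executes only if its target does
   not itself merge away in the same sweep, which defers chain merges
   (c1→c2→c3 performs c2→c3 and revisits c1 next sweep against the
   enlarged target). Sweeps repeat until none merges; the cluster count
   strictly decreases every productive sweep, so termination is
   guaranteed within the initial cluster count. Merging touches only
   representations and member-id lists, never read sequences.

## Parameters

| name | meaning | ONT default | PacBio default |
|------|---------|------------|----------------|
| k    | k-mer length (bases) | 13 | 15 |
| w    | window size (k-mer start positions) | 21 | 51 |
| T1   | HCS confidence threshold (probability) | 0.95 | 0.98 |
| T2   | join threshold: shared seeds / distinct read seeds | 0.5 | 0.5 |
| T3   | merge threshold: HCS overlap / smaller representation | 0.5 | 0.8 |

T1 reflects base-quality levels per technology (ONT's lower qualities
need a laxer gate or almost no seed passes); the higher PacBio T3 guards
against over-merging through chimeric/concatamer reads. Even and odd w
are both accepted.

## Hashing and orderings

Seed values are 64-bit: the 2-bit-encoded k-mer (A=0, C=1, G=2, T=3)
passed through the splitmix64 finalizer, a fixed avalanche-quality
bijection, so results are reproducible across runs and platforms. A
`lexicographic` ordering mode (the raw 2-bit encoding, whose integer
order is lexicographic) exists for tests and worked examples where the
selected k-mer should be predictable by eye.

One subtlety is documented rather than "fixed": with leftmost tie-breaks
the *multiset* of deduplicated canonical seed values is not exactly
invariant under reverse complementation — in repeat regions, tied
positions can deduplicate differently on the two strands — but the *set*
of values is invariant, and cluster representations and join decisions
only ever use sets. The confidence of a canonical seed always comes from
the forward-read quality substring, since qualities belong to the bases
as sequenced regardless of which strand's k-mer won.

## Numerical and degenerate-input conventions

- Seed confidences are computed as exp of windowed sums of log
  probabilities; a Phred-0 base gives probability 0 and propagates to a
  zero-confidence seed.
- T2 is inclusive (≥), so T2 = 1.0 still lets exact duplicates join; T3
  is strict (>), so T3 = 1.0 disables merging entirely.
- Join ties: smallest cluster id. Merge target ties: smallest id. Visit
  ties: smallest id. Sorting ties: input order.
- Metrics use natural-log entropies (the measures are ratios, so the
  base cancels). Conventions: homogeneity is 1 when H(classes) = 0,
  completeness is 1 when H(clusters) = 0; the adjusted Rand index of a
  degenerate contingency (zero denominator, e.g. both partitions all
  singletons) is 1 for identical partitions and 0 otherwise. Reads
  missing from the class file are scored as unique singleton classes by
  default (`unclassified="singleton"`) so every read enters the metrics;
  an `exclude` policy drops them instead.
- Output cluster ids are renumbered 0..C−1 by decreasing member count
  (ties: creation order); the TSV lists `cluster_id <tab> read_id`.

## Synthetic data generator

The generator emulates the features of long-read transcriptome data that
drive the algorithm, at desk scale: gene families are independent random
exon concatenations (so families are k-mer-disjoint for k ≫ log₄ of the
total sequence length); isoforms are ordered exon subsets all containing
a family anchor exon; reads are isoform copies with optional 5'/3'
truncation, random strand, and substitution/insertion/deletion errors.

Quality strings follow a two-regime segment model: clean segments (mean
Phred 30, mean length 200 bases) alternate with noisy segments (mean
length 50) whose mean Phred is solved numerically so that the expected
error probability E[10^(−Q/10)] of the emitted, rounded, clamped (Q ∈
[2, 50]) quality distribution equals the configured error rate; per-base
scores scatter with SD 3 around the regime mean. Errors are then
injected per base with the probability 1 − p implied by that base's own
quality, which makes quality strings statistically consistent with the
injected errors by construction and gives the T1 gate realistic material:
most error mass sits in the noisy segments, while clean segments supply
dense runs of high-confidence seeds — the structure real basecallers
produce. With a single-regime Gaussian quality model at the same mean
error rate, almost no 13-mer would pass T1 = 0.95 and the algorithm's
central mechanism would be starved, which is not how it behaves on real
data.

What the generator does **not** model: homopolymer-biased ONT errors,
signal-level artefacts, concatamers/chimeras, reverse-transcription
artefacts, per-read quality level differences, intron retention or
positional splicing realism, and expression-level imbalance beyond the
configured per-family read counts. Passing tests therefore demonstrate
the algorithm's mechanics (seed selection, representation growth,
merging, determinism) under controlled conditions, not clustering quality
on any particular real instrument's data.

The chain-family fixture (`chain_family_reads`) is the minimal structure
separating dynamic from founder-frozen representations: isoforms span
sliding 3-exon windows over exons of decreasing length, so the longest
isoform always sorts first, consecutive isoforms share about two thirds
of their seeds, and the two end isoforms share about a third — below T2.

## Problem sizes

The test suite and acceptance script run everything at desk scale: 500
simulated reads (10 families × 50 reads, ~1–2 kb each) for end-to-end
recovery, 10⁴ random instances (reads ≤ 60 bp, k ≤ 7, w ≤ 9) for
exhaustive minimizer-oracle agreement, all set partitions of ≤ 8 elements
plus random n = 50 fixtures for metric-oracle agreement, and 100 random
clusterings for merge invariants. These sizes exercise every code path
while keeping a full run in minutes on one core; the algorithm itself
streams reads once and scales to far larger inputs.

## Design choices on genuinely open points

- **HCS counting for sorting** uses seed positions, not distinct values:
  "number of HCS" most plainly counts seeds, and the choice only affects
  tie structure in the sort.
- **Join denominator D** counts distinct seed values of the read, so
  repeat-rich reads neither inflate nor deflate their join fraction.
- **"Most shared seeds"** counts distinct shared values.
- **Cluster size for merging** is |HCS| (representation size), not
  member count.
- **Equal-size merge eligibility**: allowed toward the smaller id;
  otherwise two clusters with identical representations could never
  merge.
- **Candidate enumeration** is index-driven (only clusters sharing ≥ 1
  seed are scored); an exhaustive comparison exists in the tests as an
  independent replay oracle, never in the pipeline.
- **No alignment fallback** anywhere: assignments and merges are decided
  on seed-set arithmetic only.

## Known limitations

- Zero-HCS reads (short or uniformly low-quality) each sit in their own
  cluster; no rescue pass exists.
- Very high error rates (≳ 12%) starve the HCS supply under the default
  ONT thresholds, fragmenting clusters; different T1/T2 would be needed.
- Gene families sharing true sequence (paralogs, shared domains) can
  merge if their shared HCS exceed the thresholds; the metrics module
  quantifies but does not prevent this.
- The sorting step keeps all reads in memory (the spill option re-streams
  the sorted order but sorting itself is in-memory), as does the output
  stage; external-memory variants are out of scope.
- Clustering quality on reads from an instrument whose error/quality
  structure differs strongly from the generator's two-regime model is
  not characterised here.
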