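# Methods

## Index model

The reference genome is loaded as an ordered set of contigs joined into a
single coordinate space with one `#` separator between contigs; the
separator lies outside the DNA alphabet, so no seed or alignment window
can silently span a contig boundary. The character order used throughout
is `$ < # < A < C < G < T < N`; `N` never matches any search character.

**Global index.** A conventional FM-index over the terminated concatenated
text: suffix array built by prefix doubling on numpy integer ranks
(O(n log² n), adequate for the hundreds-of-kilobase scale this package
targets), BWT, a C array, a dense Occ prefix-count matrix (one lookup per
rank query; O(n·σ) memory is a few MB at this scale), and a stride-sampled
suffix array (default stride 4) with LF-walk recovery for `locate`.
Reverse-strand matching searches the reverse-complemented read; only one
index is kept.

**Local indexes.** For every `l_init`-mer (default 20) occurring more than
`k` times (default 8), a node stores:

- *Flank sets.* The `l_ext`-length (default 16) left and right flanks of
  every occurrence, deduplicated and sorted; an occurrence whose flank
  would run off the contig or contain `N`/`#` contributes no flank on that
  side (it remains in the node's occurrence list, so nothing is lost, only
  unextensible).
- *sBWT.* For a set of m distinct equal-length strings, iteration i sorts
  the members by their i-fold left rotation; column i stores, in that
  order, the character each member exposes at backward-search step i (the
  last character of its i-rotation). Because rotation is a bijection the
  per-iteration orders are well defined, and the classical LF identity
  `C(sbwt^i, c) + Occ(sbwt^i, r, c)` maps a rank interval from iteration
  i's order to iteration i−1's; an `l_ext`-step backward search therefore
  ends in the canonical lexicographic order. The rotation-order
  permutations are materialised per iteration. Approximate search branches
  over {A,C,G,T} at each step under a Hamming budget (`max_mm` per block,
  default 1); branches on distinct characters produce disjoint intervals,
  so every member is reported with exactly one distance.
- *Relation array.* `Rel` holds one entry per distinct co-occurring
  (predecessor, successor) flank pair, sorted by rank pair, with the
  occurrence positions of the extended seed `pred + seed + succ`;
  `LtoRel[i]:LtoRel[i+1]` delimits predecessor i's block. Validating a
  candidate pair is a scan of that block. Each entry is the child
  reference: entries with more than `k` occurrences have a child node
  (built recursively, to `max_depth` 8 iterations), the rest are terminal.

Nodes are keyed by seed string, so an extended seed reachable twice would
be shared; the extension geometry (fixed center, fixed block length) makes
each extended seed's parent unique in practice. A child's occurrence list,
derived from the parent's complete list, equals the genome-wide occurrence
set of the child's seed string — the tests verify this against naive
enumeration.

## Seeding, chaining, extension

Reads are sampled every `x` nt (default 10) on both strands. Exact
`l_init`-mer lookup resolves each sample: at most `k` hits → report
directly; more → descend the local hierarchy, consuming `l_ext` read
characters per side per level, keeping every flank pair that survives the
mismatch budget *and* validates through the relation array. Extension
stops at ≤ k occurrences, no validated pair, insufficient read sequence on
either side, or `max_depth`; the deepest reached seeds are reported (all
surviving branches, to preserve sensitivity). Occurrence counts are
non-increasing along any extension chain by construction. Samples whose
initial exact lookup is empty (an error inside the window) are dropped;
the stride recovers sensitivity.

Candidate positions are projected to read-start anchors (position −
read offset), sorted per strand, and greedily grouped whenever consecutive
anchors differ by less than d (default 100 bp). Chains are ranked by
member count (ties: total seed length, then leftmost anchor, then strand —
fully deterministic), and the top K = 8 are extended.

Extension is a glocal (fit) affine-gap DP over a window spanning the
chain's anchors plus a quarter-read-length margin, clamped to the contig:
free start/end in the reference, full read consumed, either read end
soft-clippable at a flat penalty of 5 when that improves the score. The
kernel (numba-compiled) also selects the optimal end cell; traceback
yields the CIGAR. Scoring defaults are the common short-read values
match 1, mismatch 4, gap open 6, gap extend 1. A read is unmapped when no
candidate reaches 30% of the maximum possible score (this internal floor
is distinct from the 85% *evaluation* criterion). Ties between equal best
scores go to the smallest genome coordinate with MAPQ 0; otherwise
MAPQ = min(60, 60·(best − second)/best), a deterministic monotone margin
rule. The `band` field of the scoring parameters is reserved; the DP runs
full-matrix at these window sizes.

## Simulator

`simulate_genome` plants repeat families — a random unit copied at
non-overlapping random loci, each copy with independent per-base
substitution divergence — in a uniform-random background. Defaults:
200 kb genome, 20 families × 10 copies × 200 bp at 1% divergence (~20%
repeat content), mimicking the repeat-rich setting that motivates
approximate seeding. `simulate_reads` draws uniform start positions and
strands and applies, in order: SNPs (0.1%), indels (0.02%, geometric
length with mean 2), then base errors (2%) — the standard Illumina-like
rates used for evaluating resequencing aligners. Truth records keep the
pre-mutation origin. Everything is deterministic under a fixed seed.

What the simulator does *not* model: position- and cycle-dependent
quality, GC bias, coverage waves, structural variation, real repeat
taxonomies (LINEs/SINEs/segmental duplications have length and divergence
spectra a single family parameter cannot express), or quality-string
realism (qualities are constant). Passing the end-to-end thresholds here
shows the method is correct and robust at the stated error rates on
clean repeat structure, not that it matches any specific tool's numbers
on a real genome.

## Evaluation

Simulation mode: a read is *mapped* if it has at least one alignment;
an alignment is *good* if on the true contig and strand within ±5 bp
(default tolerance; indels shift coordinates, and the generator does not
record per-read offset corrections). sensitivity = mapped/reads × 100,
accuracy = good/mapped × 100. Reference mode (no truth): an alignment is
good when its re-computed score is **strictly greater** than 85% of the
maximum achievable score (read length × match reward) — a 100 bp read
scoring exactly 85 fails the criterion. At a 2% base error rate this is a
demanding bar: a read needs ≤ 2 errors to pass with these scoring
parameters, so roughly two-thirds of mapped reads qualify in simulation
even when nearly all are correctly placed.

## Problem sizes and numerical choices

The test suite and the acceptance script run the complete pipeline at
desk scale: oracle equivalence on ~1.5–3 kb genomes (where brute-force
enumeration is exact and fast), and the end-to-end evaluation on a 200 kb
genome with 10,000 100 bp reads. DP scores are exact integers (int32);
index determinism is byte-exact under fixed parameters. Degenerate
inputs: empty flank sets make a node terminal; all-N reads yield no
seeds; an empty candidate set yields an unmapped record, never an error.

## Known limitations

- Approximate extension is mismatch-only per block; indels inside an
  extension block defeat the local search (the DP stage still recovers
  most such reads via neighbouring exact seeds).
- Extension requires both flanks; a seed at the very start or end of a
  read is reported unextended even when one side could continue.
- Single-threaded; primary alignments only (no secondary/supplementary
  records, no paired-end logic).
- The index is rebuilt rather than updated; serialization is a versioned
  pickle archive intended for local reuse, not archival interchange.
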