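# mam-aligner

A repeat-aware short-read aligner built on **maximal approximate match
(MAM) seeds**, with a full synthetic evaluation pipeline.

## The problem

Short-read alignment follows the seed-and-extend paradigm: exact substrings
of the read (seeds) are looked up in an FM-index of the reference, candidate
locations are chained, and the best candidates are extended with dynamic
programming. Repetitive DNA breaks this scheme: a 20 bp seed inside a
repeat family can have hundreds of candidate locations, and the usual
escape — maximal *exact* match (MEM) seeding — fails as soon as a
sequencing error or variant interrupts the exact match.

This package extends repetitive seeds *approximately* instead. For every
initial seed string s occurring more than k times, the index stores a
**local index**:

- the deduplicated sets `pred(s, l_ext)` and `succ(s, l_ext)` of the seed's
  fixed-length left/right flanking sequences over all occurrences;
- an **sBWT** over each set — a multi-string BWT variant for equal-length
  sequences built from iterated rotation sorts (one searchable column per
  rotation level), supporting backward search with a bounded per-block
  Hamming mismatch budget via `C(sbwt^i, c)` and `Occ(sbwt^i, r, c)`;
- a **relation array** `(LtoRel, Rel)` recording which (predecessor,
  successor) flank pairs actually co-occur at a genomic occurrence, each
  pair pointing to the extended seed `s' = pred + s + succ` of the next
  iteration.

Seeding samples the read every x nt on both strands, resolves each exact
`l_init`-mer through the global FM-index, and extends repetitive seeds
block-by-block (`l_ext` per side, up to `max_mm` mismatches per block)
through the local index hierarchy until the occurrence count drops to
k or extension is impossible. Surviving candidate locations are chained by
anchor distance d, the top K chains are extended with affine-gap (Gotoh)
glocal DP (gap of length g costs `gap_open + g*gap_extend`; read ends may
be soft-clipped at a flat penalty), and the best-scoring placement is
emitted as SAM v1.6 with NM/AS tags and a margin-based MAPQ.

## Worked example

```bash
python examples/01_worked_example.py
```

The demonstration reference is a synthetic 140 bp sequence in which the
6-mer `CGACTA` occurs 7 times. With 4 bp extension blocks the local index
of that seed looks like:

```
seed CGACTA: suffix-array interval width 7
occurrence positions: [10, 30, 50, 70, 90, 110, 130]

predecessor set (6 distinct flanks of 7 occurrences):
  rank 0: AGGC  at flank positions [126]
  ...
  rank 4: TCAT  at flank positions [6, 26]   <- duplicate stored once

approximate search for TCAA (<=1 mismatch): [(4, 1), (5, 1)]

relation array (which flank pairs actually co-occur):
  pred TCAT + CGACTA + succ TGGA  at [6]
  pred TCAT + CGACTA + succ TTCC  at [26]
  ...
```

The interval width (global index), the occurrence list (local index root)
and a naive scan of the reference all agree on 7 occurrences; the flank
`TCAT` precedes two occurrences but is stored once, and the relation array
distinguishes the two extended seeds it participates in.

`examples/02_align_reads.py` aligns hand-made reads (perfect, SNP,
reverse-strand, random, from-a-repeat) and prints their placements;
`examples/03_evaluate_simulation.py` runs the whole pipeline on a 50 kb
simulated genome (1,000 reads) and printed, on this machine:

```
reads=1000 mapped=999 good=962 sensitivity=99.90% accuracy=96.30%
strict score criterion (> 85% of max): 64.86% of mapped reads
```

Sensitivity counts reads with at least one alignment; accuracy counts
mapped reads placed at their simulated origin (same contig and strand,
within 5 bp). The strict criterion instead demands an alignment score
above 85% of the maximum — at a 2% base error rate many correctly placed
reads fall below it, which is why the two accuracy notions differ.

## Command line

```bash
mam simulate sim --genome-length 200000 --n-reads 10000 --seed 1
mam index sim.fasta sim.idx
mam align sim.idx sim.fastq out.sam
mam evaluate out.sam --truth sim.truth.tsv
mam evaluate out.sam --reference sim.fasta     # 85%-of-max score criterion
```

## Layout

- `src/mam/sequences.py` — FASTA/FASTQ I/O, genome coordinates, alphabet
- `src/mam/fm_global.py` — suffix array, BWT, global FM-index
- `src/mam/local_index.py` — flank sets, sBWT, relation array, hierarchy
- `src/mam/seeding.py` — MAM seeding (sampling + approximate extension)
- `src/mam/chain_extend.py` — chaining, affine-gap DP, MAPQ
- `src/mam/alignio.py` — SAM emission
- `src/mam/simeval.py` — genome/read simulator and evaluation metrics
- `src/mam/cli.py` — `mam {index, align, simulate, evaluate}`

See `docs/methods.md` for the model, parameter defaults and limitations.
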