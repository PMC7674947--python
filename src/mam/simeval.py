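"""Synthetic genome/read simulation and the sensitivity/accuracy evaluation.

The simulator emulates an Illumina-like resequencing experiment on a
repeat-rich genome: a uniform-random background with planted repeat
families (a random unit copied at non-overlapping loci, each copy with
independent per-base divergence), and reads drawn uniformly from either
strand carrying SNPs (default rate 0.1%), short indels (0.02%, geometric
length with mean 2) and sequencing base errors (2%).  Truth records keep
each read's pre-mutation origin.

Evaluation follows the standard simulated-read protocol: a read is
*mapped* if it has at least one alignment, and an alignment is *good* if
it is placed at the true position (same contig and strand, within a small
positional tolerance).  sensitivity = #mapped/#reads x 100%;
accuracy = #good/#mapped x 100%.  For data without a truth set, an
alignment is counted good when its re-computed alignment score exceeds a
fraction (default 85%) of the maximum achievable score for its length —
strictly: a 100 bp read with match reward 1 must score higher than 85.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pysam

from mam.chain_extend import ScoringParams, rescore_cigar
from mam.sequences import Genome, Read, reverse_complement

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class RepeatFamily:
    copies: int = 10
    unit_length: int = 200
    divergence: float = 0.01


def default_families(n: int = 20) -> tuple[RepeatFamily, ...]:
    """20 families x 10 copies x 200 bp = 40 kb of repeats (~20% of the
    default 200 kb genome)."""
    return tuple(RepeatFamily() for _ in range(n))


@dataclass
class SimParams:
    genome_length: int = 200_000
    families: tuple[RepeatFamily, ...] = field(default_factory=default_families)
    n_reads: int = 10_000
    read_length: int = 100
    snp_rate: float = 0.001
    indel_rate: float = 0.0002
    base_error_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.snp_rate, self.indel_rate, self.base_error_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")


@dataclass
class TruthRecord:
    read_id: str
    contig: str
    pos: int  # 0-based leftmost coordinate of the read's origin
    strand: str


@dataclass
class EvalResult:
    n_reads: int
    n_mapped: int
    n_good: int

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.n_mapped / self.n_reads if self.n_reads else 0.0

    @property
    def accuracy(self) -> float:
        return 100.0 * self.n_good / self.n_mapped if self.n_mapped else 0.0

    def summary(self) -> str:
        return (
            f"reads={self.n_reads} mapped={self.n_mapped} good={self.n_good} "
            f"sensitivity={self.sensitivity:.2f}% accuracy={self.accuracy:.2f}%"
        )


def _random_bases(rng: np.random.Generator, n: int) -> np.ndarray:
    return _BASES[rng.integers(0, 4, size=n)]


def _substitute(rng: np.random.Generator, base: str) -> str:
    others = [b for b in "ACGT" if b != base]
    return others[int(rng.integers(0, 3))]


def simulate_genome(params: SimParams) -> tuple[Genome, list[dict]]:
    """Uniform-random background with planted, annotated repeat copies."""
    rng = np.random.default_rng(params.seed)
    G = params.genome_length
    total_repeat = sum(f.copies * f.unit_length for f in params.families)
    if total_repeat > G:
        raise ValueError("repeat families exceed the genome length")
    seq = _random_bases(rng, G)
    occupied: list[tuple[int, int]] = []
    annotation: list[dict] = []
    for fi, fam in enumerate(params.families):
        unit = _random_bases(rng, fam.unit_length)
        for ci in range(fam.copies):
            for _ in range(1000):
                start = int(rng.integers(0, G - fam.unit_length + 1))
                end = start + fam.unit_length
                if all(end <= s or start >= e for s, e in occupied):
                    break
            else:
                raise ValueError("could not place repeat copies without overlap")
            occupied.append((start, end))
            copy = unit.copy()
            div = rng.random(fam.unit_length) < fam.divergence
            for p in np.nonzero(div)[0]:
                copy[p] = _substitute(rng, copy[p])
            seq[start:end] = copy
            annotation.append(
                {"contig": "chrS", "start": start, "end": end, "family": fi, "copy": ci}
            )
    genome = Genome([("chrS", "".join(seq))])
    return genome, annotation


def simulate_reads(
    genome: Genome, params: SimParams
) -> tuple[list[Read], list[TruthRecord]]:
    """Reads with SNPs, indels and base errors; truth keeps the origin."""
    rng = np.random.default_rng([params.seed, 1])
    L = params.read_length
    slack = 20
    lengths = np.array([len(s) for _, s in genome.contigs], dtype=float)
    if L > lengths.max():
        raise ValueError("read length exceeds every contig")
    usable = np.maximum(lengths - L - slack, 0.0)
    if usable.sum() == 0:
        usable = np.maximum(lengths - L, 0.0) + 1e-9
    weights = usable / usable.sum()
    reads: list[Read] = []
    truth: list[TruthRecord] = []
    for ri in range(params.n_reads):
        while True:
            ci = int(rng.choice(len(genome.contigs), p=weights))
            name, cseq = genome.contigs[ci]
            max_start = max(len(cseq) - L - slack, 0)
            pos0 = int(rng.integers(0, max_start + 1))
            template = cseq[pos0 : pos0 + L + slack]
            out: list[str] = []
            i = 0
            draws = rng.random(len(template))
            while len(out) < L and i < len(template):
                r = draws[i]
                if r < params.indel_rate:
                    g = int(rng.geometric(0.5))  # mean length 2
                    if rng.random() < 0.5:
                        out.extend(_random_bases(rng, g))
                    else:
                        i += g
                        continue
                elif r < params.indel_rate + params.snp_rate:
                    out.append(_substitute(rng, template[i]))
                    i += 1
                else:
                    out.append(template[i])
                    i += 1
            if len(out) >= L:
                break
        read_seq = list(out[:L])
        errs = np.nonzero(rng.random(L) < params.base_error_rate)[0]
        for p in errs:
            read_seq[p] = _substitute(rng, read_seq[p])
        seq = "".join(read_seq)
        strand = "+" if rng.random() < 0.5 else "-"
        if strand == "-":
            seq = reverse_complement(seq)
        rid = f"sim_{ri}"
        reads.append(Read(rid, seq, "I" * L))
        truth.append(TruthRecord(rid, name, pos0, strand))
    return reads, truth


def write_truth(truth: list[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        for t in truth:
            fh.write(f"{t.read_id}\t{t.contig}\t{t.pos}\t{t.strand}\n")


def read_truth(path: str) -> list[TruthRecord]:
    out = []
    with open(path) as fh:
        for line in fh:
            rid, contig, pos, strand = line.rstrip("\n").split("\t")
            out.append(TruthRecord(rid, contig, int(pos), strand))
    return out


def evaluate_sim(sam_path: str, truth: list[TruthRecord], tolerance: int = 5) -> EvalResult:
    """Sensitivity/accuracy of a SAM file against simulation truth.

    "True position" means: same contig, same strand, and leftmost position
    within ``tolerance`` bp of the origin (indels shift coordinates).
    """
    by_id = {t.read_id: t for t in truth}
    mapped: set[str] = set()
    good: set[str] = set()
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            t = by_id.get(rec.query_name)
            if t is None:
                raise ValueError(f"read {rec.query_name!r} absent from the truth set")
            if rec.is_unmapped:
                continue
            mapped.add(rec.query_name)
            strand = "-" if rec.is_reverse else "+"
            if (
                rec.reference_name == t.contig
                and strand == t.strand
                and abs(rec.reference_start - t.pos) <= tolerance
            ):
                good.add(rec.query_name)
    return EvalResult(n_reads=len(by_id), n_mapped=len(mapped), n_good=len(good))


def evaluate_real(
    sam_path: str,
    genome: Genome,
    frac: float = 0.85,
    scoring: ScoringParams | None = None,
) -> float:
    """Percentage of mapped records whose re-computed alignment score is
    strictly higher than ``frac`` of the maximum score for their length."""
    if not 0.0 < frac <= 1.0:
        raise ValueError("score fraction must lie in (0, 1]")
    scoring = scoring or ScoringParams()
    n_mapped = 0
    n_good = 0
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        for rec in fh:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            n_mapped += 1
            seq = rec.query_sequence
            pos0 = genome.local_to_global(rec.reference_name, rec.reference_start)
            score, _ = rescore_cigar(genome, pos0, rec.cigarstring, seq, scoring)
            if score > frac * len(seq) * scoring.match:
                n_good += 1
    return 100.0 * n_good / n_mapped if n_mapped else 0.0
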