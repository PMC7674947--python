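"""Seed chaining, affine-gap extension and best-alignment selection.

Seed hits are projected to read-start anchors (genome position minus read
offset), sorted, and greedily grouped into chains whenever consecutive
anchors lie within distance ``d``.  Chains are ranked by the number of
supporting seed hits and the top ``K`` are extended with a glocal
("fit") affine-gap dynamic program: the whole read must be consumed,
except that either end may be soft-clipped at a flat penalty when the
clip improves the score.  A gap of length g costs gap_open + g*gap_extend.
The highest-scoring placement wins; ties go to the smallest genome
coordinate with mapping quality 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from mam.local_index import MAMIndex
from mam.seeding import Seed, SeedingParams, seed_read
from mam.sequences import Genome, Read, encode, reverse_complement

_NEG = -(10**6)


@dataclass
class ScoringParams:
    """Alignment scoring.  All penalties are magnitudes (>= 0)."""

    match: int = 1
    mismatch: int = 4
    gap_open: int = 6
    gap_extend: int = 1
    clip: int = 5  # flat soft-clip penalty per clipped read end
    band: int = 0  # 0 = full-matrix DP (banding not applied at desk scale)
    chain_dist: int = 100  # d: anchors closer than this share a chain
    top_chains: int = 8  # K: chains taken to DP extension
    floor_frac: float = 0.3  # unmapped if best score < floor_frac * L * match

    def __post_init__(self) -> None:
        if self.match <= 0 or min(self.mismatch, self.gap_open, self.gap_extend, self.clip) < 0:
            raise ValueError("invalid scoring parameters")


@dataclass
class Chain:
    strand: str
    anchors: list[int]
    members: list[tuple[Seed, int]]  # (seed, genome position)

    @property
    def count(self) -> int:
        return len(self.members)

    @property
    def total_seed_length(self) -> int:
        return sum(s.length for s, _ in self.members)


@dataclass
class Alignment:
    read_id: str
    contig: str | None
    pos: int  # 1-based leftmost reference position; 0 when unmapped
    strand: str
    score: int
    cigar: str
    nm: int
    mapq: int
    is_mapped: bool
    read_seq: str = ""
    read_qual: str | None = None


def chain_seeds(seeds: list[Seed], d: int) -> list[Chain]:
    """Group seed hits whose read-start anchors are within ``d`` of their
    sorted neighbour, separately per strand."""
    if d <= 0:
        raise ValueError("chain distance must be positive")
    chains: list[Chain] = []
    for strand in ("+", "-"):
        hits = []
        for s in seeds:
            if s.strand != strand:
                continue
            for p in s.positions:
                hits.append((int(p) - s.read_start, s, int(p)))
        hits.sort(key=lambda t: t[0])
        cur: Chain | None = None
        for anchor, s, p in hits:
            if cur is None or anchor - cur.anchors[-1] >= d:
                cur = Chain(strand=strand, anchors=[], members=[])
                chains.append(cur)
            cur.anchors.append(anchor)
            cur.members.append((s, p))
    return chains


def rank_chains(chains: list[Chain]) -> list[Chain]:
    """Stable descending sort by member count; ties broken by total seed
    length (desc), then leftmost anchor (asc), then strand."""
    return sorted(
        chains,
        key=lambda c: (-c.count, -c.total_seed_length, min(c.anchors), c.strand),
    )


@njit(cache=False)
def _fit_dp(q, w, match, mismatch, gap_open, gap_ext, clip):  # pragma: no cover
    L, W = len(q), len(w)
    H = np.full((L + 1, W + 1), _NEG, np.int32)
    I = np.full((L + 1, W + 1), _NEG, np.int32)
    D = np.full((L + 1, W + 1), _NEG, np.int32)
    tbH = np.zeros((L + 1, W + 1), np.uint8)
    tbI = np.zeros((L + 1, W + 1), np.uint8)
    tbD = np.zeros((L + 1, W + 1), np.uint8)
    for j in range(W + 1):
        H[0, j] = 0  # free alignment start anywhere in the window
    for i in range(1, L + 1):
        for j in range(W + 1):
            # insertion (read base against a gap in the reference)
            a = H[i - 1, j] - gap_open - gap_ext
            b = I[i - 1, j] - gap_ext
            if a >= b:
                I[i, j] = a
                tbI[i, j] = 0
            else:
                I[i, j] = b
                tbI[i, j] = 1
            h = I[i, j]
            src = 2
            if j > 0:
                # deletion (reference base against a gap in the read)
                a = H[i, j - 1] - gap_open - gap_ext
                b = D[i, j - 1] - gap_ext
                if a >= b:
                    D[i, j] = a
                    tbD[i, j] = 0
                else:
                    D[i, j] = b
                    tbD[i, j] = 1
                qa = q[i - 1]
                wb = w[j - 1]
                if qa == wb and qa >= 2 and qa <= 5:
                    s = match
                else:
                    s = -mismatch
                diag = H[i - 1, j - 1] + s
                if diag > h:
                    h = diag
                    src = 1
                if D[i, j] > h:
                    h = D[i, j]
                    src = 3
            if i < L and -clip > h:
                h = -clip  # fresh start: head soft clip of read[0:i]
                src = 4
            H[i, j] = h
            tbH[i, j] = src
    # end selection: full read consumed, or tail soft-clipped at flat cost
    best = _NEG
    end_i, end_j = L, 0
    for j in range(W + 1):
        if H[L, j] > best:
            best = H[L, j]
            end_i, end_j = L, j
    for i in range(1, L):
        for j in range(W + 1):
            sc = H[i, j] - clip
            if sc > best:
                best = sc
                end_i, end_j = i, j
    return H, I, D, tbH, tbI, tbD, best, end_i, end_j


def affine_gap_extend(
    ref_window: str, read: str, params: ScoringParams
) -> tuple[int, str, int]:
    """Optimal glocal alignment of ``read`` against ``ref_window``.

    Returns ``(score, cigar, ref_offset)`` where ``ref_offset`` is the
    0-based window column at which the alignment consumes its first
    reference base.  The read is fully consumed except for optionally
    soft-clipped ends (flat penalty each).
    """
    if not ref_window or not read:
        raise ValueError("empty sequence given to the aligner")
    q = encode(read)
    w = encode(ref_window)
    H, I, D, tbH, tbI, tbD, best, end_i, end_j = _fit_dp(
        q, w, params.match, params.mismatch, params.gap_open, params.gap_extend, params.clip
    )
    L = len(q)
    best, end_i, end_j = int(best), int(end_i), int(end_j)
    # traceback
    ops: list[tuple[str, int]] = []

    def push(op: str, n: int = 1) -> None:
        if n == 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    push("S", L - end_i)
    i, j, state = end_i, end_j, 0  # state 0=H, 1=I, 2=D
    while True:
        if state == 0:
            src = tbH[i, j]
            if src == 0:  # i == 0: alignment start, no head clip
                break
            if src == 4:  # fresh start: head clip of read[0:i]
                push("S", i)
                i = 0
                break
            if src == 1:
                push("M")
                i, j = i - 1, j - 1
            elif src == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            push("I")
            prev = tbI[i, j]
            i -= 1
            state = 0 if prev == 0 else 1
        else:
            push("D")
            prev = tbD[i, j]
            j -= 1
            state = 0 if prev == 0 else 2
    ref_offset = j
    cigar = "".join(f"{n}{op}" for op, n in reversed(ops))
    return best, cigar, ref_offset


def rescore_cigar(
    genome: Genome, pos0: int, cigar: str, read: str, params: ScoringParams
) -> tuple[int, int]:
    """Re-derive (score, edit distance) by walking a CIGAR against the
    reference.  Soft clips cost the flat clip penalty and do not count
    toward the edit distance."""
    import re

    score, nm = 0, 0
    ri, gi = 0, pos0
    n = len(genome.concat)
    for num, op in re.findall(r"(\d+)([MIDS])", cigar):
        ln = int(num)
        if op == "M":
            if gi + ln > n:
                raise ValueError("CIGAR overruns the reference")
            for t in range(ln):
                a, b = read[ri + t], genome.concat[gi + t]
                if a == b and a in "ACGT":
                    score += params.match
                else:
                    score -= params.mismatch
                    nm += 1
            ri += ln
            gi += ln
        elif op == "I":
            score -= params.gap_open + ln * params.gap_extend
            nm += ln
            ri += ln
        elif op == "D":
            if gi + ln > n:
                raise ValueError("CIGAR overruns the reference")
            score -= params.gap_open + ln * params.gap_extend
            nm += ln
            gi += ln
        elif op == "S":
            score -= params.clip
            ri += ln
    if ri != len(read):
        raise ValueError("CIGAR does not consume the full read")
    return score, nm


def compute_mapq(best_score: int, second_score: int, params: ScoringParams) -> int:
    """Phred-scaled mapping confidence from the score margin.

    0 when the best placement is tied; capped at 60; monotone in
    (best - second) for a fixed best score.
    """
    if best_score <= 0:
        return 0
    second = max(second_score, 0)
    if second >= best_score:
        return 0
    return min(60, int(round(60.0 * (best_score - second) / best_score)))


def _genome_codes(index: MAMIndex) -> np.ndarray:
    codes = getattr(index, "_concat_codes", None)
    if codes is None:
        codes = encode(index.genome.concat)
        index._concat_codes = codes
    return codes


def align_read(
    index: MAMIndex,
    read: Read,
    seed_params: SeedingParams | None = None,
    scoring: ScoringParams | None = None,
) -> Alignment:
    """Seed, chain, DP-extend the top chains and pick the best placement."""
    scoring = scoring or ScoringParams()
    genome = index.genome
    unmapped = Alignment(
        read_id=read.id, contig=None, pos=0, strand="+", score=0, cigar="*",
        nm=0, mapq=0, is_mapped=False, read_seq=read.seq, read_qual=read.qual,
    )
    if len(read.seq) == 0:
        return unmapped
    seeds = seed_read(index, read, seed_params)
    if not seeds:
        return unmapped
    chains = rank_chains(chain_seeds(seeds, scoring.chain_dist))[: scoring.top_chains]
    L = len(read.seq)
    margin = max(L // 4, 8)
    oriented = {"+": read.seq, "-": reverse_complement(read.seq)}
    candidates: dict[tuple[str, int], tuple[int, str, int]] = {}  # (strand,pos0)->(score,cigar,nm)
    for chain in chains:
        mid = chain.anchors[len(chain.anchors) // 2]
        try:
            contig, _ = genome.global_to_local(min(max(mid, 0), len(genome.concat) - 1))
        except IndexError:
            continue
        ci = genome.names.index(contig)
        c_start = genome.offsets[ci]
        c_end = c_start + genome.length_of(contig)
        w_start = max(min(chain.anchors) - margin, c_start)
        w_end = min(max(chain.anchors) + L + margin, c_end)
        if w_end - w_start < 1:
            continue
        window = genome.concat[w_start:w_end]
        score, cigar, ref_off = affine_gap_extend(window, oriented[chain.strand], scoring)
        pos0 = w_start + ref_off
        key = (chain.strand, pos0)
        if key not in candidates or score > candidates[key][0]:
            _, nm = rescore_cigar(genome, pos0, cigar, oriented[chain.strand], scoring)
            candidates[key] = (score, cigar, nm)
    if not candidates:
        return unmapped
    ranked = sorted(
        candidates.items(), key=lambda kv: (-kv[1][0], kv[0][1], kv[0][0])
    )
    (strand, pos0), (score, cigar, nm) = ranked[0]
    floor = scoring.floor_frac * L * scoring.match
    if score < floor:
        return unmapped
    if len(ranked) > 1:
        second = ranked[1][1][0]
        mapq = 0 if second == score else compute_mapq(score, second, scoring)
    else:
        mapq = compute_mapq(score, 0, scoring)
    # leading soft clip does not consume reference: POS points at first M/D base
    contig, local = genome.global_to_local(pos0)
    return Alignment(
        read_id=read.id, contig=contig, pos=local + 1, strand=strand, score=score,
        cigar=cigar, nm=nm, mapq=mapq, is_mapped=True,
        read_seq=read.seq, read_qual=read.qual,
    )
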