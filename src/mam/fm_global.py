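"""Global FM-index: suffix array, BWT, C/Occ, exact backward search, locate.

The suffix array is built with prefix doubling on numpy integer ranks
(O(n log^2 n)), which comfortably handles desk-scale genomes (hundreds of
kilobases) without compiled dependencies.  Occ is stored as a dense
prefix-count matrix — at these scales the O(n·sigma) memory is a few
megabytes and keeps every rank query a single array lookup.  The suffix
array is sampled with a fixed stride; unsampled entries are recovered by
LF-stepping to the nearest sampled row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from mam.sequences import CODE, Genome, TERMINATOR, encode

SIGMA = 7  # $, #, A, C, G, T, N


def build_suffix_array(text: str) -> np.ndarray:
    """Suffix array of ``text``, which must end with a unique terminator
    lexicographically smaller than every other character.

    Returns the permutation of [0, n) listing suffix start positions in
    increasing lexicographic order (``sa[0]`` is the terminator position).
    """
    if not text.endswith(TERMINATOR):
        raise ValueError("text must end with the terminator character")
    if TERMINATOR in text[:-1]:
        raise ValueError("terminator occurs before the end of the text")
    codes = encode(text).astype(np.int64)
    return _suffix_array_from_codes(codes)


def _suffix_array_from_codes(codes: np.ndarray) -> np.ndarray:
    n = len(codes)
    rank = codes.copy()
    sa = np.argsort(rank, kind="stable")
    k = 1
    tmp = np.empty(n, dtype=np.int64)
    while True:
        # sort by (rank[i], rank[i+k]) using the shifted rank as secondary key
        second = np.full(n, -1, dtype=np.int64)
        second[: n - k] = rank[k:]
        order = np.lexsort((second, rank))
        # recompute ranks: same pair as the previous entry -> same rank
        tmp[order[0]] = 0
        prev, cur = order[:-1], order[1:]
        diff = (rank[cur] != rank[prev]) | (second[cur] != second[prev])
        tmp[cur] = np.cumsum(diff)
        rank, tmp = tmp.copy(), tmp
        if rank[order[-1]] == n - 1:
            sa = order
            break
        k *= 2
    return sa.astype(np.int64)


@dataclass
class SAInterval:
    """Half-open interval [bg, ed) of suffix-array rows; width = occurrence count."""

    bg: int
    ed: int

    @property
    def width(self) -> int:
        return self.ed - self.bg

    def is_empty(self) -> bool:
        return self.ed <= self.bg


@dataclass
class FMIndex:
    """FM-index over the terminated concatenated genome text."""

    text: str
    sa_stride: int = 4
    bwt_codes: np.ndarray = field(init=False, repr=False)
    counts: np.ndarray = field(init=False, repr=False)  # total count per code
    C: np.ndarray = field(init=False, repr=False)  # chars lexically smaller than c
    occ: np.ndarray = field(init=False, repr=False)  # occ[r, c] = count of c in bwt[:r]
    sa_sample: np.ndarray = field(init=False, repr=False)
    sampled_mask: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        sa = build_suffix_array(self.text)
        codes = encode(self.text)
        n = len(codes)
        self.bwt_codes = codes[(sa - 1) % n]
        self.counts = np.bincount(self.bwt_codes, minlength=SIGMA).astype(np.int64)
        self.C = np.concatenate(([0], np.cumsum(self.counts)[:-1]))
        occ = np.zeros((n + 1, SIGMA), dtype=np.int64)
        onehot = np.zeros((n, SIGMA), dtype=np.int64)
        onehot[np.arange(n), self.bwt_codes] = 1
        occ[1:] = np.cumsum(onehot, axis=0)
        self.occ = occ
        self.sampled_mask = (sa % self.sa_stride) == 0
        self.sa_sample = sa[self.sampled_mask]
        # row index -> position in sa_sample, for sampled rows only
        self._sample_rank = np.cumsum(self.sampled_mask) - 1

    @property
    def n(self) -> int:
        return len(self.bwt_codes)

    def lf(self, row: int) -> int:
        c = self.bwt_codes[row]
        return int(self.C[c] + self.occ[row, c])

    def suffix_position(self, row: int) -> int:
        """Recover sa[row] by LF-walking to the nearest sampled entry."""
        steps = 0
        while not self.sampled_mask[row]:
            row = self.lf(row)
            steps += 1
        return int(self.sa_sample[self._sample_rank[row]]) + steps

    def reconstruct_text(self) -> str:
        """Invert the BWT by LF-walking (sanity check of index integrity)."""
        from mam.sequences import decode

        out = np.empty(self.n, dtype=np.uint8)
        row = 0  # row 0 corresponds to the suffix "$"
        for i in range(self.n - 1, -1, -1):
            out[i] = self.bwt_codes[row]
            row = self.lf(row)
        # the walk yields the rotation starting at "$"; undo it
        return decode(out[1:]) + TERMINATOR


def build_fm_index(genome: Genome, sa_stride: int = 4) -> FMIndex:
    """Build the global FM-index over ``genome.concat`` + terminator."""
    if len(genome.concat) == 0:
        raise ValueError("cannot index an empty genome")
    return FMIndex(genome.concat + TERMINATOR, sa_stride=sa_stride)


def backward_search_global(fm: FMIndex, pattern: str) -> SAInterval:
    """Exact backward search; the interval width equals the occurrence count
    of ``pattern`` in the forward text.  Absent patterns (including any
    containing N) yield an empty interval."""
    bg, ed = 0, fm.n
    for ch in reversed(pattern):
        c = CODE.get(ch)
        if c is None or c == CODE["N"]:
            return SAInterval(0, 0)
        bg = int(fm.C[c] + fm.occ[bg, c])
        ed = int(fm.C[c] + fm.occ[ed, c])
        if bg >= ed:
            return SAInterval(0, 0)
    return SAInterval(bg, ed)


def locate(fm: FMIndex, interval: SAInterval) -> np.ndarray:
    """Genome start positions (0-based, ascending) for a suffix-array interval."""
    if interval.bg < 0 or interval.ed > fm.n:
        raise IndexError("suffix-array interval out of bounds")
    positions = [fm.suffix_position(r) for r in range(interval.bg, interval.ed)]
    return np.array(sorted(positions), dtype=np.int64)
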