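"""Maximal approximate match (MAM) seeding.

A read is sampled every ``x`` nt on both strands.  Each sampled
``l_init``-mer is looked up exactly in the global FM-index; seeds with at
most ``k`` occurrences are reported directly, while repetitive seeds are
extended through the local index hierarchy: the read's next ``l_ext``
characters on each side are searched approximately (bounded Hamming
mismatches) in the node's predecessor/successor sBWTs, surviving flank
pairs are validated through the relation array, and extension descends
into the paired child seed until the occurrence count drops to ``k`` or
below, the read runs out of flank characters, no pair validates, or the
indexed depth is exhausted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from mam.fm_global import backward_search_global, locate
from mam.local_index import MAMIndex
from mam.sequences import Read, reverse_complement

_DNA = frozenset("ACGT")


@dataclass
class SeedingParams:
    """Seeding knobs.

    l_init: initial exact seed length (bp).
    l_ext:  per-side extension block length (bp); must match the index.
    x:      sampling stride of seed start offsets on the read (nt).
    k:      occurrence threshold separating unique-enough from repetitive.
    max_mm: Hamming mismatch budget per extension block per side.
    """

    l_init: int = 20
    l_ext: int = 16
    x: int = 10
    k: int = 8
    max_mm: int = 1

    def __post_init__(self) -> None:
        if min(self.l_init, self.l_ext, self.x) < 1 or self.k < 1 or self.max_mm < 0:
            raise ValueError("invalid seeding parameters")


@dataclass
class Seed:
    """A read interval matched (approximately) to a set of genome positions.

    ``read_start`` and ``length`` are in the orientation of the searched
    strand; ``positions`` are global concat coordinates of the match start;
    ``mismatches`` bounds the Hamming distance of every reported position.
    """

    read_start: int
    length: int
    strand: str  # "+" | "-"
    positions: np.ndarray
    mismatches: int = 0

    @property
    def occ(self) -> int:
        return len(self.positions)


def extract_initial_seeds(read: Read, params: SeedingParams) -> list[tuple[int, str]]:
    """Sampled (read_start, strand) pairs: offsets 0, x, 2x, ... while the
    ``l_init`` window fits, on both strands."""
    n = len(read.seq)
    if n < params.l_init:
        return []
    starts = list(range(0, n - params.l_init + 1, params.x))
    return [(s, st) for st in ("+", "-") for s in starts]


def extend_seed(
    index: MAMIndex, oriented_read: str, read_start: int, strand: str, params: SeedingParams
) -> list[Seed]:
    """Seed one sampled offset: exact initial lookup, then iterative
    approximate extension through the local index hierarchy.

    Returns zero or more seeds (extension can branch when several flank
    pairs survive the mismatch budget).
    """
    l_init, l_ext = params.l_init, params.l_ext
    if not 0 <= read_start <= len(oriented_read) - l_init:
        raise IndexError("seed start out of range for this read")
    kmer = oriented_read[read_start : read_start + l_init]
    if not _DNA.issuperset(kmer):
        return []
    iv = backward_search_global(index.fm, kmer)
    if iv.is_empty():
        return []
    if iv.width <= params.k:
        return [Seed(read_start, l_init, strand, locate(index.fm, iv), 0)]
    node = index.roots.get(kmer)
    if node is None:  # index built with different parameters; fall back to exact hit
        return [Seed(read_start, l_init, strand, locate(index.fm, iv), 0)]

    results: list[Seed] = []
    frontier = [(node, read_start, read_start + l_init, 0)]
    while frontier:
        cur, rl, rr, mm = frontier.pop()
        extensible = (
            not cur.is_leaf()
            and cur.pred_sbwt is not None
            and cur.succ_sbwt is not None
            and rl >= l_ext
            and rr + l_ext <= len(oriented_read)
        )
        if not extensible:
            results.append(Seed(rl, rr - rl, strand, cur.occ_positions, mm))
            continue
        left = oriented_read[rl - l_ext : rl]
        right = oriented_read[rr : rr + l_ext]
        pred_hits = cur.pred_sbwt.backward_search(left, params.max_mm)
        succ_hits = cur.succ_sbwt.backward_search(right, params.max_mm)
        validated = []
        for rp, mp in pred_hits:
            for rs, ms in succ_hits:
                entry = cur.ra.validate_pair(rp, rs)
                if entry is not None:
                    validated.append((entry, mp + ms))
        if not validated:
            results.append(Seed(rl, rr - rl, strand, cur.occ_positions, mm))
            continue
        for entry, dm in validated:
            child = cur.children.get(entry.child_seed)
            if child is not None:  # still repetitive: keep extending
                frontier.append((child, rl - l_ext, rr + l_ext, mm + dm))
            else:  # occurrence count dropped to <= k: terminal seed
                results.append(
                    Seed(rl - l_ext, (rr - rl) + 2 * l_ext, strand, entry.positions, mm + dm)
                )
    return results


def seed_read(index: MAMIndex, read: Read, params: SeedingParams | None = None) -> list[Seed]:
    """All MAM seeds of a read over both strands, duplicates merged."""
    if params is None:
        params = SeedingParams(l_init=index.l_init, l_ext=index.l_ext, k=index.k)
    oriented = {"+": read.seq}
    try:
        oriented["-"] = reverse_complement(read.seq)
    except ValueError:
        return []  # non-DNA read
    seen: dict[tuple, Seed] = {}
    for start, strand in extract_initial_seeds(read, params):
        for seed in extend_seed(index, oriented[strand], start, strand, params):
            if seed.occ == 0:
                continue
            key = (strand, seed.read_start, seed.length, seed.positions.tobytes())
            prev = seen.get(key)
            if prev is None or seed.mismatches < prev.mismatches:
                seen[key] = seed
    return list(seen.values())
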