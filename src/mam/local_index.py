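"""Hierarchical local indexes for repetitive seeds.

For every seed string that occurs more than ``k`` times in the genome, a
local index node stores the seed's deduplicated left and right flanking
sequences of fixed length ``l_ext`` (its predecessor and successor sets),
an sBWT over each set supporting approximate backward search, and a
relation array recording which (predecessor, successor) flank pairs
actually co-occur at a genomic occurrence of the seed.  A validated pair
defines the extended seed ``pred + seed + succ`` of the next iteration;
nodes for extended seeds that are still repetitive are built recursively,
producing the hierarchical index used by MAM seeding.

The sBWT indexes a set of *m* distinct strings of equal length *L* via
*L* rotation sorts: iteration *i* orders the members by their *i*-fold
left rotation, and column *i* stores, in that order, the character each
member contributes at backward-search step *i* (the last character of
its *i*-rotation).  Because the rotation sorts are related exactly as the
sorted rotations of a classical Burrows-Wheeler matrix, the usual
LF-mapping ``C(sbwt^i, c) + Occ(sbwt^i, r, c)`` carries a rank interval
from iteration *i*'s order to iteration *i-1*'s order, and a full
*L*-step backward search ends with ranks in the canonical (iteration-0,
lexicographic) order.  Approximate search branches over the alphabet at
every step under a bounded Hamming mismatch budget.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from mam.fm_global import FMIndex, build_fm_index
from mam.sequences import CODE, Genome, encode

SIGMA = 7
DNA_CODES = (CODE["A"], CODE["C"], CODE["G"], CODE["T"])
_DNA = frozenset("ACGT")


@dataclass
class LocalSeqSet:
    """Deduplicated, lexicographically sorted fixed-length flank sequences.

    ``positions[r]`` lists the genome start positions of ``seqs[r]`` itself
    (so ``genome[p : p + l_ext] == seqs[r]``); flanks truncated by a contig
    boundary, or containing N or a separator, are excluded.
    """

    side: str  # "predecessor" | "successor"
    l_ext: int
    seqs: list[str]
    positions: list[np.ndarray]

    def __len__(self) -> int:
        return len(self.seqs)

    def rank_of(self, seq: str) -> int | None:
        return self._rank_map.get(seq)

    @property
    def _rank_map(self) -> dict[str, int]:
        if not hasattr(self, "_rank_cache"):
            self._rank_cache = {s: i for i, s in enumerate(self.seqs)}
        return self._rank_cache


def _gen_flanks(
    genome: Genome, seed_positions: np.ndarray, seed_len: int, l_ext: int, side: str
) -> LocalSeqSet:
    if l_ext <= 0:
        raise ValueError("l_ext must be positive")
    concat = genome.concat
    n = len(concat)
    by_seq: dict[str, list[int]] = {}
    for p in np.asarray(seed_positions, dtype=np.int64):
        p = int(p)
        start = p - l_ext if side == "predecessor" else p + seed_len
        end = start + l_ext
        if start < 0 or end > n:
            continue
        flank = concat[start:end]
        if not _DNA.issuperset(flank):  # N or contig separator: no indexed flank
            continue
        by_seq.setdefault(flank, []).append(start)
    seqs = sorted(by_seq)
    positions = [np.array(sorted(by_seq[s]), dtype=np.int64) for s in seqs]
    return LocalSeqSet(side=side, l_ext=l_ext, seqs=seqs, positions=positions)


def gen_pred(genome: Genome, seed_positions, seed_len: int, l_ext: int) -> LocalSeqSet:
    """Deduplicated ``l_ext``-length left flanks of the seed occurrences."""
    return _gen_flanks(genome, seed_positions, seed_len, l_ext, "predecessor")


def gen_succ(genome: Genome, seed_positions, seed_len: int, l_ext: int) -> LocalSeqSet:
    """Deduplicated ``l_ext``-length right flanks of the seed occurrences."""
    return _gen_flanks(genome, seed_positions, seed_len, l_ext, "successor")


class SBWT:
    """Multi-string BWT over a set of distinct equal-length sequences.

    ``columns[i]`` is sbwt^i; ``occs[i][r, c]`` counts character ``c`` among
    the first ``r`` entries of column ``i`` and ``Cs[i][c]`` counts column
    entries lexically smaller than ``c``.  ``order_maps[i]`` is the
    permutation placing the canonical members into iteration ``i``'s
    rotation-sorted order.
    """

    def __init__(self, seqs: list[str]):
        if not seqs:
            raise ValueError("empty sequence set")
        L = len(seqs[0])
        if any(len(s) != L for s in seqs):
            raise ValueError("sequences must share one length")
        if sorted(seqs) != list(seqs) or len(set(seqs)) != len(seqs):
            raise ValueError("sequences must be distinct and sorted")
        self.seqs = list(seqs)
        self.length = L
        m = len(seqs)
        mat = np.vstack([encode(s) for s in seqs])  # (m, L)
        self.order_maps = []
        self.columns = []
        self.occs = []
        self.Cs = []
        for i in range(L):
            rot = np.roll(mat, -i, axis=1)
            order = np.lexsort(rot.T[::-1])  # rows lexicographically
            col = mat[order, (i - 1) % L]
            occ = np.zeros((m + 1, SIGMA), dtype=np.int64)
            onehot = np.zeros((m, SIGMA), dtype=np.int64)
            onehot[np.arange(m), col] = 1
            occ[1:] = np.cumsum(onehot, axis=0)
            counts = occ[m]
            C = np.concatenate(([0], np.cumsum(counts)[:-1]))
            self.order_maps.append(order)
            self.columns.append(col)
            self.occs.append(occ)
            self.Cs.append(C)

    def __len__(self) -> int:
        return len(self.seqs)

    def occ(self, i: int, r: int, c: int) -> int:
        """Occurrences of code ``c`` among the first ``r`` entries of column ``i``."""
        if not 0 <= i < self.length:
            raise IndexError(f"iteration {i} outside [0, {self.length})")
        if not 0 <= r <= len(self.seqs):
            raise IndexError("prefix length out of range")
        return int(self.occs[i][r, c])

    def backward_search(self, pattern: str, max_mm: int = 0) -> list[tuple[int, int]]:
        """Members within Hamming distance ``max_mm`` of ``pattern``.

        Returns ``(rank, mismatches)`` pairs, ranks in the canonical sorted
        order, ascending.  Pattern characters outside {A,C,G,T} (e.g. N)
        match nothing and cost a mismatch on every branch.
        """
        L = self.length
        if len(pattern) != L:
            raise ValueError(f"pattern length {len(pattern)} != {L}")
        if max_mm < 0:
            raise ValueError("mismatch budget must be >= 0")
        pat = encode(pattern)
        m = len(self.seqs)
        out: list[tuple[int, int]] = []
        # state: (j, bg, ed, mm) — interval in iteration-(j mod L) order after
        # consuming pattern[j:]
        stack = [(L, 0, m, 0)]
        while stack:
            j, bg, ed, mm = stack.pop()
            if j == 0:
                out.extend((r, mm) for r in range(bg, ed))
                continue
            col = j % L
            want = pat[j - 1]
            C, occ = self.Cs[col], self.occs[col]
            for c in DNA_CODES:
                cost = 0 if c == want else 1
                if mm + cost > max_mm:
                    continue
                nbg = int(C[c] + occ[bg, c])
                ned = int(C[c] + occ[ed, c])
                if nbg < ned:
                    stack.append((j - 1, nbg, ned, mm + cost))
        return sorted(out)


def build_sbwt(seqset: LocalSeqSet) -> SBWT:
    """sBWT over a flank set's member sequences."""
    return SBWT(seqset.seqs)


def sbwt_occ(sbwt: SBWT, i: int, r: int, ch: str) -> int:
    """Occ(sbwt^i, r, ch): count of ``ch`` among the first ``r`` entries of column ``i``."""
    return sbwt.occ(i, r, CODE[ch])


def backward_search_local(sbwt: SBWT, pattern: str, max_mm: int) -> list[tuple[int, int]]:
    """Approximate membership query; see :meth:`SBWT.backward_search`."""
    return sbwt.backward_search(pattern, max_mm)


@dataclass
class RelEntry:
    """One co-occurring (predecessor, successor) flank pair of a seed."""

    rank_pred: int
    rank_succ: int
    child_seed: str
    positions: np.ndarray  # start positions of the extended seed

    @property
    def n_occ(self) -> int:
        return len(self.positions)


@dataclass
class RelationArray:
    """(LtoRel, Rel) pairing structure between predecessor and successor flanks.

    ``Rel`` holds one entry per distinct co-occurring flank pair, sorted by
    (rank_pred, rank_succ); ``LtoRel[i] : LtoRel[i+1]`` delimits the block
    of entries whose predecessor rank is ``i``.
    """

    LtoRel: np.ndarray
    Rel: list[RelEntry]

    def validate_pair(self, rank_pred: int, rank_succ: int) -> RelEntry | None:
        if not 0 <= rank_pred < len(self.LtoRel) - 1:
            raise IndexError("predecessor rank out of range")
        if rank_succ < 0:
            raise IndexError("successor rank out of range")
        for idx in range(int(self.LtoRel[rank_pred]), int(self.LtoRel[rank_pred + 1])):
            if self.Rel[idx].rank_succ == rank_succ:
                return self.Rel[idx]
        return None


def build_relation_array(
    pred: LocalSeqSet,
    succ: LocalSeqSet,
    genome: Genome,
    seed: str,
    seed_positions: np.ndarray,
) -> RelationArray:
    """Pair each seed occurrence's left and right flank ranks.

    Occurrences lacking an indexed flank on either side contribute no entry;
    occurrences sharing the same flank pair collapse into one entry whose
    position list gathers all of them.
    """
    l_ext = pred.l_ext
    if succ.l_ext != l_ext:
        raise ValueError("predecessor/successor flank lengths differ")
    seed_len = len(seed)
    pred_rank = pred._rank_map
    succ_rank = succ._rank_map
    concat = genome.concat
    n = len(concat)
    pairs: dict[tuple[int, int], list[int]] = {}
    for p in np.asarray(seed_positions, dtype=np.int64):
        p = int(p)
        if p - l_ext < 0 or p + seed_len + l_ext > n:
            continue
        pseq = concat[p - l_ext : p]
        sseq = concat[p + seed_len : p + seed_len + l_ext]
        rp = pred_rank.get(pseq)
        rs = succ_rank.get(sseq)
        if rp is None or rs is None:
            continue
        pairs.setdefault((rp, rs), []).append(p - l_ext)
    rel: list[RelEntry] = []
    lto = np.zeros(len(pred) + 1, dtype=np.int64)
    for (rp, rs) in sorted(pairs):
        child_seed = pred.seqs[rp] + seed + succ.seqs[rs]
        rel.append(
            RelEntry(rp, rs, child_seed, np.array(sorted(pairs[(rp, rs)]), dtype=np.int64))
        )
    counts = np.zeros(len(pred), dtype=np.int64)
    for e in rel:
        counts[e.rank_pred] += 1
    lto[1:] = np.cumsum(counts)
    return RelationArray(LtoRel=lto, Rel=rel)


def validate_pair(ra: RelationArray, rank_pred: int, rank_succ: int) -> RelEntry | None:
    """The relation entry (child reference) for a flank pair, or None if the
    pair never co-occurs at a genomic position."""
    return ra.validate_pair(rank_pred, rank_succ)


@dataclass
class LocalIndexNode:
    """Local index of one repetitive seed string."""

    seed: str
    occ_positions: np.ndarray
    depth: int
    pred: LocalSeqSet | None = None
    succ: LocalSeqSet | None = None
    pred_sbwt: SBWT | None = None
    succ_sbwt: SBWT | None = None
    ra: RelationArray | None = None
    children: dict[str, "LocalIndexNode"] = field(default_factory=dict)

    @property
    def n_occ(self) -> int:
        return len(self.occ_positions)

    def is_leaf(self) -> bool:
        return self.ra is None


@dataclass
class MAMIndex:
    """Hierarchical MAM-index: global FM-index plus local index nodes rooted
    at every repetitive initial k-mer."""

    genome: Genome
    fm: FMIndex
    roots: dict[str, LocalIndexNode]
    nodes: dict[str, LocalIndexNode]
    l_init: int
    l_ext: int
    k: int
    max_depth: int

    def save(self, path: str) -> None:
        import pickle

        with open(path, "wb") as fh:
            fh.write(b"MAMIDX1\n")
            pickle.dump(self, fh, protocol=4)

    @staticmethod
    def load(path: str) -> "MAMIndex":
        import pickle

        with open(path, "rb") as fh:
            magic = fh.readline()
            if magic != b"MAMIDX1\n":
                raise ValueError(f"{path} is not a MAM index archive")
            idx = pickle.load(fh)
        if not isinstance(idx, MAMIndex):
            raise ValueError(f"{path} does not contain a MAM index")
        return idx


def repetitive_kmers(genome: Genome, l_init: int, k: int) -> dict[str, np.ndarray]:
    """All ``l_init``-mers of the concatenated genome (pure A/C/G/T) with more
    than ``k`` occurrences, mapped to their sorted occurrence positions."""
    codes = encode(genome.concat)
    if len(codes) < l_init:
        raise ValueError("genome shorter than the initial seed length")
    windows = sliding_window_view(codes, l_init)
    valid = ((windows >= CODE["A"]) & (windows <= CODE["T"])).all(axis=1)
    idx = np.nonzero(valid)[0]
    if len(idx) == 0:
        return {}
    uniq, inverse, counts = np.unique(
        windows[idx], axis=0, return_inverse=True, return_counts=True
    )
    out: dict[str, np.ndarray] = {}
    rep = np.nonzero(counts > k)[0]
    if len(rep) == 0:
        return {}
    order = np.argsort(inverse, kind="stable")
    starts = np.searchsorted(inverse[order], np.arange(len(uniq)))
    ends = np.append(starts[1:], len(inverse))
    from mam.sequences import decode

    for u in rep:
        kmer = decode(uniq[u])
        out[kmer] = np.sort(idx[order[starts[u] : ends[u]]]).astype(np.int64)
    return out


def _build_node(
    genome: Genome,
    seed: str,
    positions: np.ndarray,
    depth: int,
    l_ext: int,
    k: int,
    max_depth: int,
    nodes: dict[str, LocalIndexNode],
) -> LocalIndexNode:
    node = LocalIndexNode(seed=seed, occ_positions=positions, depth=depth)
    nodes[seed] = node
    if depth >= max_depth:
        return node  # leaf: no further extension indexed
    pred = gen_pred(genome, positions, len(seed), l_ext)
    succ = gen_succ(genome, positions, len(seed), l_ext)
    node.pred, node.succ = pred, succ
    if len(pred) == 0 or len(succ) == 0:
        return node  # no occurrence has both flanks; not extensible
    node.pred_sbwt = build_sbwt(pred)
    node.succ_sbwt = build_sbwt(succ)
    node.ra = build_relation_array(pred, succ, genome, seed, positions)
    for entry in node.ra.Rel:
        if entry.n_occ > k:
            child = nodes.get(entry.child_seed)
            if child is None:
                child = _build_node(
                    genome, entry.child_seed, entry.positions, depth + 1, l_ext, k,
                    max_depth, nodes,
                )
            node.children[entry.child_seed] = child
    return node


def build_mam_index(
    genome: Genome,
    l_init: int = 20,
    l_ext: int = 16,
    k: int = 8,
    max_depth: int = 8,
    sa_stride: int = 4,
) -> MAMIndex:
    """Build the full hierarchical index: the global FM-index plus a local
    index tree rooted at every ``l_init``-mer occurring more than ``k`` times."""
    if l_init <= 0 or l_ext <= 0:
        raise ValueError("l_init and l_ext must be positive")
    if k < 1:
        raise ValueError("occurrence threshold k must be >= 1")
    if len(genome.concat) < l_init:
        raise ValueError("genome shorter than the initial seed length")
    fm = build_fm_index(genome, sa_stride=sa_stride)
    nodes: dict[str, LocalIndexNode] = {}
    roots: dict[str, LocalIndexNode] = {}
    for kmer, positions in repetitive_kmers(genome, l_init, k).items():
        roots[kmer] = _build_node(genome, kmer, positions, 0, l_ext, k, max_depth, nodes)
    return MAMIndex(
        genome=genome, fm=fm, roots=roots, nodes=nodes,
        l_init=l_init, l_ext=l_ext, k=k, max_depth=max_depth,
    )
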