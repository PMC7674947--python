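"""Independent brute-force oracles used to validate the index and aligner.

Everything here works directly on plain strings with naive enumeration and
never touches the package's index structures, so agreement between the two
routes is meaningful.
"""

from __future__ import annotations

_DNA = set("ACGT")


def naive_suffix_array(text: str) -> list[int]:
    return sorted(range(len(text)), key=lambda i: text[i:])


def naive_occurrences(text: str, pattern: str) -> list[int]:
    """All start positions of exact occurrences of ``pattern`` in ``text``."""
    if not pattern:
        return []
    out, start = [], 0
    while True:
        i = text.find(pattern, start)
        if i < 0:
            return out
        out.append(i)
        start = i + 1


def hamming(a: str, b: str) -> int:
    assert len(a) == len(b)
    return sum(x != y or x not in _DNA for x, y in zip(a, b))


def brute_flanks(concat: str, positions, seed_len: int, l_ext: int, side: str):
    """Deduplicated flank set: {flank: sorted flank start positions}."""
    out: dict[str, list[int]] = {}
    for p in positions:
        p = int(p)
        start = p - l_ext if side == "predecessor" else p + seed_len
        end = start + l_ext
        if start < 0 or end > len(concat):
            continue
        flank = concat[start:end]
        if not _DNA.issuperset(flank):
            continue
        out.setdefault(flank, []).append(start)
    return {s: sorted(v) for s, v in out.items()}


def brute_hamming_filter(seqs: list[str], pattern: str, max_mm: int):
    """(rank, distance) for every member within Hamming distance max_mm."""
    return [
        (r, hamming(s, pattern))
        for r, s in enumerate(seqs)
        if hamming(s, pattern) <= max_mm
    ]


def brute_mam_seeds(
    concat: str,
    read: str,
    start: int,
    l_init: int,
    l_ext: int,
    k: int,
    max_mm: int,
    max_depth: int,
):
    """Blockwise-approximate maximal match enumeration for one sampled offset.

    Mirrors the seeding contract by direct genome scanning: exact initial
    l_init-mer occurrences; while the string is repetitive (> k occurrences),
    group surviving occurrences by their extended string, where an
    occurrence survives when both l_ext flanks exist, contain only A/C/G/T,
    and each lies within ``max_mm`` mismatches of the read's corresponding
    block.  Returns a set of (read_start, length, positions, mismatches).
    """
    kmer = read[start : start + l_init]
    if not _DNA.issuperset(kmer):
        return set()
    positions = naive_occurrences(concat, kmer)
    if not positions:
        return set()
    if len(positions) <= k:
        return {(start, l_init, tuple(positions), 0)}
    results = set()
    frontier = [(start, start + l_init, tuple(positions), 0, 0)]
    while frontier:
        rl, rr, poss, mm, depth = frontier.pop()
        if depth >= max_depth or rl < l_ext or rr + l_ext > len(read):
            results.add((rl, rr - rl, poss, mm))
            continue
        left = read[rl - l_ext : rl]
        right = read[rr : rr + l_ext]
        seed_len = rr - rl
        groups: dict[str, tuple[list[int], int]] = {}
        for p in poss:
            ps, pe = p - l_ext, p + seed_len + l_ext
            if ps < 0 or pe > len(concat):
                continue
            pred = concat[ps:p]
            succ = concat[p + seed_len : pe]
            if not _DNA.issuperset(pred + succ):
                continue
            dp, ds = hamming(pred, left), hamming(succ, right)
            if dp <= max_mm and ds <= max_mm:
                ext = concat[ps:pe]
                if ext in groups:
                    groups[ext][0].append(ps)
                else:
                    groups[ext] = ([ps], dp + ds)
        if not groups:
            results.add((rl, rr - rl, poss, mm))
            continue
        for ext, (child_pos, dm) in groups.items():
            entry = (rl - l_ext, rr + l_ext, tuple(sorted(child_pos)), mm + dm, depth + 1)
            if len(child_pos) > k:
                frontier.append(entry)
            else:
                results.add((entry[0], entry[1] - entry[0], entry[2], entry[3]))
    return results


def gotoh_score(ref: str, read: str, match: int, mismatch: int,
                gap_open: int, gap_ext: int, clip: int) -> int:
    """Textbook affine-gap glocal alignment score, computed forwards with
    plain Python lists: free reference start/end, full read consumed except
    for optional flat-penalty soft clips at either end."""
    L, W = len(read), len(ref)
    NEG = float("-inf")
    # best[i][j]: read[:i] handled (aligned or head-clipped), ref ends at j
    H = [[NEG] * (W + 1) for _ in range(L + 1)]
    E = [[NEG] * (W + 1) for _ in range(L + 1)]  # gap in ref (insertion)
    F = [[NEG] * (W + 1) for _ in range(L + 1)]  # gap in read (deletion)
    for j in range(W + 1):
        H[0][j] = 0
    for i in range(1, L + 1):
        for j in range(W + 1):
            E[i][j] = max(H[i - 1][j] - gap_open - gap_ext, E[i - 1][j] - gap_ext)
            best = E[i][j]
            if j > 0:
                F[i][j] = max(H[i][j - 1] - gap_open - gap_ext, F[i][j - 1] - gap_ext)
                a, b = read[i - 1], ref[j - 1]
                s = match if (a == b and a in _DNA) else -mismatch
                best = max(best, H[i - 1][j - 1] + s, F[i][j])
            if i < L:
                best = max(best, -clip)  # head soft clip of read[:i]
            H[i][j] = best
    out = max(H[L][j] for j in range(W + 1))
    for i in range(1, L):
        out = max(out, max(H[i][j] for j in range(W + 1)) - clip)
    return int(out)
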