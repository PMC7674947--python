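"""Genome and read containers, FASTA/FASTQ I/O, alphabet utilities.

Contigs are concatenated into one coordinate space with a single ``#``
separator character between contigs; the separator lies outside the DNA
alphabet so no index search can ever match across a contig boundary.
Internal coordinates are 0-based half-open throughout; SAM emission
converts to 1-based (see :mod:`mam.alignio`).
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

SEPARATOR = "#"
TERMINATOR = "$"

# Integer codes used by the index layer.  The terminator sorts below
# everything, the contig separator below the DNA alphabet, and N above it
# (N never matches a search character either way).
CODE = {TERMINATOR: 0, SEPARATOR: 1, "A": 2, "C": 3, "G": 4, "T": 5, "N": 6}
DECODE = {v: k for k, v in CODE.items()}
A_CODE, T_CODE = CODE["A"], CODE["T"]

_ENC_TABLE = np.full(256, CODE["N"], dtype=np.uint8)
for _ch, _code in CODE.items():
    _ENC_TABLE[ord(_ch)] = _code

_RC_TABLE = str.maketrans("ACGTN", "TGCAN")
_VALID = frozenset("ACGTN")


def encode(seq: str) -> np.ndarray:
    """Encode a text over {$,#,A,C,G,T,N} as a uint8 array."""
    return _ENC_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode(codes: Iterable[int]) -> str:
    return "".join(DECODE[int(c)] for c in codes)


def reverse_complement(seq: str) -> str:
    """Reverse complement over {A,C,G,T,N}; N maps to N.

    Raises ``ValueError`` on characters outside the alphabet.
    """
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"non-DNA characters in sequence: {sorted(bad)}")
    return seq.translate(_RC_TABLE)[::-1]


@dataclass
class Genome:
    """An ordered collection of named contigs sharing one global coordinate space.

    ``concat`` joins the uppercased contig sequences with a single ``#``
    between consecutive contigs (no trailing separator, no terminator);
    ``offsets[i]`` is the global start of contig *i* in ``concat``.
    """

    contigs: list[tuple[str, str]]
    concat: str = field(init=False)
    offsets: list[int] = field(init=False)

    def __post_init__(self) -> None:
        names = [n for n, _ in self.contigs]
        if len(set(names)) != len(names):
            raise ValueError("duplicate contig names")
        self.contigs = [(n, s.upper()) for n, s in self.contigs]
        parts, offsets, pos = [], [], 0
        for i, (name, seq) in enumerate(self.contigs):
            if i:
                parts.append(SEPARATOR)
                pos += 1
            offsets.append(pos)
            parts.append(seq)
            pos += len(seq)
        self.concat = "".join(parts)
        self.offsets = offsets

    def __len__(self) -> int:
        return len(self.concat)

    @property
    def names(self) -> list[str]:
        return [n for n, _ in self.contigs]

    def length_of(self, name: str) -> int:
        for n, s in self.contigs:
            if n == name:
                return len(s)
        raise KeyError(name)

    def global_to_local(self, pos: int) -> tuple[str, int]:
        """Map a global concat coordinate to (contig name, 0-based local position)."""
        if not 0 <= pos < len(self.concat):
            raise IndexError(f"global position {pos} out of range")
        i = bisect.bisect_right(self.offsets, pos) - 1
        name, seq = self.contigs[i]
        local = pos - self.offsets[i]
        if local >= len(seq):  # separator position
            raise IndexError(f"global position {pos} falls on a contig separator")
        return name, local

    def local_to_global(self, name: str, pos: int) -> int:
        for i, (n, s) in enumerate(self.contigs):
            if n == name:
                if not 0 <= pos < len(s):
                    raise IndexError(f"position {pos} out of range for contig {name}")
                return self.offsets[i] + pos
        raise KeyError(name)

    def fetch(self, start: int, end: int) -> str:
        return self.concat[start:end]


@dataclass
class Read:
    id: str
    seq: str
    qual: str | None = None

    def __post_init__(self) -> None:
        self.seq = self.seq.upper()
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise ValueError(
                f"read {self.id}: quality length {len(self.qual)} != sequence length {len(self.seq)}"
            )

    def __len__(self) -> int:
        return len(self.seq)


def read_fasta(path: str) -> Genome:
    """Load a (multi-)FASTA file into a :class:`Genome`.

    Sequences are uppercased (soft-masking ignored) and record order is
    preserved.
    """
    try:
        records = list(SeqIO.parse(path, "fasta"))
    except ValueError as exc:
        raise ValueError(f"malformed FASTA in {path}: {exc}") from exc
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return Genome([(r.id, str(r.seq).upper()) for r in records])


def write_fasta(genome: Genome, path: str) -> None:
    records = [SeqRecord(Seq(seq), id=name, description="") for name, seq in genome.contigs]
    SeqIO.write(records, path, "fasta")


def read_fastq(path: str) -> list[Read]:
    """Load 4-line FASTQ records; leading ``@`` is stripped from ids by the parser."""
    reads = []
    try:
        for rec in SeqIO.parse(path, "fastq"):
            qual = "".join(chr(q + 33) for q in rec.letter_annotations["phred_quality"])
            reads.append(Read(rec.id, str(rec.seq).upper(), qual))
    except ValueError as exc:
        raise ValueError(f"malformed FASTQ in {path}: {exc}") from exc
    return reads


def write_fastq(reads: Iterable[Read], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
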