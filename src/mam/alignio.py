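"""SAM emission (v1.6, text) via pysam.

Conventions: POS is 1-based; reverse-strand records store the
reverse-complemented read sequence with the quality string reversed;
unmapped reads are emitted with FLAG 4, POS 0 and CIGAR ``*`` so that
mapping-rate accounting can be done from the SAM alone.  NM carries the
edit distance and AS the alignment score.
"""

from __future__ import annotations

import sys
from typing import Iterable

import pysam

from mam.chain_extend import Alignment
from mam.sequences import Genome, reverse_complement


def sam_header(genome: Genome, command_line: str | None = None) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": name, "LN": len(seq)} for name, seq in genome.contigs],
        "PG": [
            {
                "ID": "mam",
                "PN": "mam",
                "CL": command_line if command_line is not None else " ".join(sys.argv),
            }
        ],
    }


def _to_segment(
    aln: Alignment, header: pysam.AlignmentHeader, genome: Genome
) -> pysam.AlignedSegment:
    seg = pysam.AlignedSegment(header)
    seg.query_name = aln.read_id
    if not aln.is_mapped:
        seg.flag = 4
        seg.reference_id = -1
        seg.reference_start = -1
        seg.mapping_quality = 0
        seg.query_sequence = aln.read_seq or None
        if aln.read_qual:
            seg.query_qualities = pysam.qualitystring_to_array(aln.read_qual)
        return seg
    if aln.contig not in genome.names:
        raise ValueError(f"alignment contig {aln.contig!r} not present in the genome")
    reverse = aln.strand == "-"
    seg.flag = 16 if reverse else 0
    seg.reference_id = header.get_tid(aln.contig)
    seg.reference_start = aln.pos - 1
    seg.mapping_quality = aln.mapq
    seg.cigarstring = aln.cigar
    seq = reverse_complement(aln.read_seq) if reverse else aln.read_seq
    seg.query_sequence = seq
    if aln.read_qual:
        qual = aln.read_qual[::-1] if reverse else aln.read_qual
        seg.query_qualities = pysam.qualitystring_to_array(qual)
    seg.set_tag("NM", aln.nm, "i")
    seg.set_tag("AS", aln.score, "i")
    return seg


def write_sam(
    alignments: Iterable[Alignment],
    genome: Genome,
    path: str,
    command_line: str | None = None,
) -> None:
    """Write alignments as a SAM v1.6 text file with @HD/@SQ/@PG header."""
    header = pysam.AlignmentHeader.from_dict(sam_header(genome, command_line))
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for aln in alignments:
            fh.write(_to_segment(aln, header, genome))
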