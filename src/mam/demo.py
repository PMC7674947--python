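"""Small synthetic worked example used in the documentation and tests.

``DEMO_REFERENCE`` is a synthetic 140 bp reference constructed so that the
6-mer seed ``CGACTA`` occurs exactly 7 times on the forward strand and its
4 bp predecessor set contains a duplicated flank (``TCAT``), exercising
flank deduplication, the sBWT and the relation array end to end at a size
small enough to verify by eye.
"""

from mam.sequences import Genome

DEMO_SEED = "CGACTA"
DEMO_L_EXT = 4

# seven 20 bp blocks: 10 bp prefix + CGACTA + 4 bp suffix
DEMO_REFERENCE = (
    "GGTATATCATCGACTATGGA"
    "ATTGGATCATCGACTATTCC"
    "TTACCGAGGTCGACTAAGTC"
    "CCGTTGTGAACGACTATGGA"
    "AATCGTCCTGCGACTACATG"
    "GTTAAGATTCCGACTAGGAT"
    "TGCCATAGGCCGACTAACCT"
)

DEMO_SEED_POSITIONS = (10, 30, 50, 70, 90, 110, 130)


def demo_genome() -> Genome:
    """The 140 bp synthetic worked-example reference as a single contig."""
    return Genome([("demo", DEMO_REFERENCE)])
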