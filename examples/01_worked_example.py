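"""Worked example: the local index of one repetitive seed.

Builds the MAM-index of the 140 bp demonstration reference at toy
parameters (6 bp initial seeds, 4 bp extension blocks, occurrence
threshold 2) and walks through the local index of the seed CGACTA:
its occurrence list, deduplicated flank sets, sBWT search and the
relation array that pairs the flanks.
"""

from mam.demo import DEMO_SEED, demo_genome
from mam.fm_global import backward_search_global, locate
from mam.local_index import build_mam_index

genome = demo_genome()
index = build_mam_index(genome, l_init=6, l_ext=4, k=2)

iv = backward_search_global(index.fm, DEMO_SEED)
print(f"seed {DEMO_SEED}: suffix-array interval width {iv.width}")
print(f"occurrence positions: {[int(p) for p in locate(index.fm, iv)]}")

root = index.roots[DEMO_SEED]
print(f"\npredecessor set ({len(root.pred)} distinct flanks of 7 occurrences):")
for r, s in enumerate(root.pred.seqs):
    print(f"  rank {r}: {s}  at flank positions {[int(p) for p in root.pred.positions[r]]}")
print(f"successor set: {root.succ.seqs}")

# approximate search in the predecessor sBWT: one mismatch allowed
query = "TCAA"  # TCAT with a mismatched last base
hits = root.pred_sbwt.backward_search(query, max_mm=1)
print(f"\napproximate search for {query} (<=1 mismatch): {hits}")
print("  -> (rank, mismatches); rank 4 is TCAT, the duplicated flank")

print("\nrelation array (which flank pairs actually co-occur):")
for e in root.ra.Rel:
    print(f"  pred {root.pred.seqs[e.rank_pred]} + {DEMO_SEED} + "
          f"succ {root.succ.seqs[e.rank_succ]}  at {[int(p) for p in e.positions]}")
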