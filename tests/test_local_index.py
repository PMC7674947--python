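import numpy as np
import pytest

from mam.demo import DEMO_SEED, DEMO_SEED_POSITIONS, demo_genome
from mam.local_index import (
    SBWT,
    backward_search_local,
    build_mam_index,
    build_relation_array,
    build_sbwt,
    gen_pred,
    gen_succ,
    repetitive_kmers,
    sbwt_occ,
    validate_pair,
)
from mam.sequences import Genome

from .conftest import random_dna, small_repeat_genome
from .oracles import brute_flanks, brute_hamming_filter, hamming, naive_occurrences


@pytest.fixture(scope="module")
def demo():
    g = demo_genome()
    pos = np.array(DEMO_SEED_POSITIONS)
    return g, pos


class TestFlankSets:
    def test_demo_predecessors_deduplicated(self, demo):
        g, pos = demo
        pred = gen_pred(g, pos, len(DEMO_SEED), 4)
        assert "TCAT" in pred.seqs
        assert len(pred.seqs) == 6  # 7 occurrences, one duplicated flank
        assert len(pred.positions[pred.rank_of("TCAT")]) == 2

    def test_demo_successors_deduplicated(self, demo):
        g, pos = demo
        succ = gen_succ(g, pos, len(DEMO_SEED), 4)
        assert len(succ.seqs) == 6
        for r, s in enumerate(succ.seqs):
            for p in succ.positions[r]:
                assert g.concat[p : p + 4] == s

    def test_boundary_occurrences_drop_their_flank(self):
        g = Genome([("c", "ACGTACGTAA")])
        pred = gen_pred(g, [0, 4], 4, 4)
        assert pred.seqs == ["ACGT"]  # position 0 has no left flank
        succ = gen_succ(g, [0, 4], 4, 4)
        assert succ.seqs == ["ACGT"]  # position 4's right flank is only 2 bp

    def test_invalid_l_ext_rejected(self, demo):
        g, pos = demo
        with pytest.raises(ValueError):
            gen_pred(g, pos, 6, 0)

    @pytest.mark.parametrize("side,fn", [("predecessor", gen_pred), ("successor", gen_succ)])
    def test_matches_brute_force_on_random_genomes(self, side, fn):
        for seed in range(5):
            rng = np.random.default_rng(seed)
            g = Genome([("c", random_dna(rng, 500))])
            kmer = g.concat[40:45]
            pos = naive_occurrences(g.concat, kmer)
            got = fn(g, pos, 5, 4)
            expect = brute_flanks(g.concat, pos, 5, 4, side)
            assert got.seqs == sorted(expect)
            for r, s in enumerate(got.seqs):
                assert list(got.positions[r]) == expect[s]


class TestSBWT:
    def test_single_member(self):
        sb = SBWT(["ACGT"])
        assert all(len(c) == 1 for c in sb.columns)
        assert sb.backward_search("ACGT", 0) == [(0, 0)]
        assert sb.backward_search("ACGG", 0) == []

    def test_demo_pred_set_search_contract(self, demo):
        g, pos = demo
        pred = gen_pred(g, pos, len(DEMO_SEED), 4)
        sb = build_sbwt(pred)
        for r, s in enumerate(pred.seqs):
            assert sb.backward_search(s, 0) == [(r, 0)]

    def test_occ_endpoints_and_bounds(self, demo):
        g, pos = demo
        sb = build_sbwt(gen_pred(g, pos, len(DEMO_SEED), 4))
        m = len(sb)
        for ch in "ACGT":
            assert sbwt_occ(sb, 0, 0, ch) == 0
            total = sum(1 for r in range(m) if sbwt_occ(sb, 2, r + 1, ch) > sbwt_occ(sb, 2, r, ch))
            assert sbwt_occ(sb, 2, m, ch) == total
        with pytest.raises(IndexError):
            sbwt_occ(sb, 4, 0, "A")

    def test_membership_exhaustive_on_random_set(self):
        rng = np.random.default_rng(7)
        seqs = sorted({random_dna(rng, 6) for _ in range(20)})
        sb = SBWT(seqs)
        for r, s in enumerate(seqs):
            assert sb.backward_search(s, 0) == [(r, 0)]
        for _ in range(50):
            q = random_dna(rng, 6)
            assert sb.backward_search(q, 0) == brute_hamming_filter(seqs, q, 0)

    @pytest.mark.parametrize("max_mm", [0, 1, 2])
    def test_approximate_search_equals_hamming_filter(self, max_mm):
        rng = np.random.default_rng(11 + max_mm)
        seqs = sorted({random_dna(rng, 8) for _ in range(30)})
        sb = SBWT(seqs)
        for _ in range(100):
            q = random_dna(rng, 8)
            assert sb.backward_search(q, max_mm) == brute_hamming_filter(seqs, q, max_mm)

    def test_n_in_pattern_costs_a_mismatch_everywhere(self):
        sb = SBWT(["ACGT"])
        assert sb.backward_search("ACGN", 0) == []
        assert sb.backward_search("ACGN", 1) == [(0, 1)]

    def test_ragged_lengths_rejected(self):
        with pytest.raises(ValueError):
            SBWT(["ACG", "ACGT"])


class TestRelationArray:
    def test_single_occurrence(self):
        g = Genome([("c", "AAAACGTACGTTTTT")])
        pos = [4]
        seed = g.concat[4:8]
        pred = gen_pred(g, pos, 4, 4)
        succ = gen_succ(g, pos, 4, 4)
        ra = build_relation_array(pred, succ, g, seed, np.array(pos))
        assert list(ra.LtoRel) == [0, 1]
        assert len(ra.Rel) == 1
        assert ra.Rel[0].child_seed == g.concat[0:12]

    def test_demo_pairing_contract(self, demo):
        g, pos = demo
        pred = gen_pred(g, pos, len(DEMO_SEED), 4)
        succ = gen_succ(g, pos, len(DEMO_SEED), 4)
        ra = build_relation_array(pred, succ, g, DEMO_SEED, pos)
        assert int(ra.LtoRel[-1]) == len(ra.Rel)
        assert (np.diff(ra.LtoRel) >= 0).all()
        # every occurrence validates through its true flank pair
        for p in pos:
            rp = pred.rank_of(g.concat[p - 4 : p])
            rs = succ.rank_of(g.concat[p + 6 : p + 10])
            entry = validate_pair(ra, rp, rs)
            assert entry is not None and p - 4 in entry.positions

    def test_never_adjacent_pair_fails(self, demo):
        g, pos = demo
        pred = gen_pred(g, pos, len(DEMO_SEED), 4)
        succ = gen_succ(g, pos, len(DEMO_SEED), 4)
        ra = build_relation_array(pred, succ, g, DEMO_SEED, pos)
        true_pairs = {
            (pred.rank_of(g.concat[p - 4 : p]), succ.rank_of(g.concat[p + 6 : p + 10]))
            for p in pos
        }
        for rp in range(len(pred)):
            for rs in range(len(succ)):
                entry = validate_pair(ra, rp, rs)
                assert (entry is not None) == ((rp, rs) in true_pairs)
        with pytest.raises(IndexError):
            validate_pair(ra, len(pred), 0)


class TestMAMIndex:
    def test_unique_genome_has_no_roots(self):
        g = Genome([("c", "ACGTTGCAATTGGCCAACCGGT")])
        idx = build_mam_index(g, l_init=6, l_ext=2, k=1)
        assert idx.roots == {}

    def test_demo_root_for_repetitive_seed(self, demo_index):
        root = demo_index.roots[DEMO_SEED]
        assert root.n_occ == 7
        assert list(root.occ_positions) == list(DEMO_SEED_POSITIONS)

    def test_too_short_genome_rejected(self):
        with pytest.raises(ValueError):
            build_mam_index(Genome([("c", "ACG")]), l_init=6, l_ext=2, k=2)

    def test_node_occurrences_match_naive_counts(self):
        g = small_repeat_genome(3)
        idx = build_mam_index(g, l_init=8, l_ext=4, k=3, max_depth=6)
        assert idx.roots  # planted repeats must produce local indexes
        for seed, node in idx.nodes.items():
            assert list(node.occ_positions) == naive_occurrences(g.concat, seed)

    def test_hierarchical_consistency_and_monotonicity(self):
        g = small_repeat_genome(4)
        idx = build_mam_index(g, l_init=8, l_ext=4, k=3, max_depth=6)
        for node in idx.nodes.values():
            parent_pos = set(int(p) for p in node.occ_positions)
            for child in node.children.values():
                assert child.n_occ <= node.n_occ
                shifted = {int(p) + idx.l_ext for p in child.occ_positions}
                assert shifted <= parent_pos

    def test_relation_completeness(self):
        """Every occurrence with both flanks in-bounds validates to a child
        entry; the others are accounted for by boundary/N losses."""
        g = small_repeat_genome(5)
        idx = build_mam_index(g, l_init=8, l_ext=4, k=3, max_depth=6)
        checked = 0
        for node in idx.nodes.values():
            if node.ra is None:
                continue
            accounted = 0
            for p in node.occ_positions:
                p = int(p)
                lo, hi = p - idx.l_ext, p + len(node.seed) + idx.l_ext
                if lo < 0 or hi > len(g.concat):
                    accounted += 1
                    continue
                rp = node.pred.rank_of(g.concat[lo:p])
                rs = node.succ.rank_of(g.concat[p + len(node.seed) : hi])
                entry = validate_pair(node.ra, rp, rs)
                assert entry is not None and lo in entry.positions
                accounted += 1
                checked += 1
            assert accounted == node.n_occ
        assert checked > 0

    def test_repetitive_kmer_enumeration_matches_counts(self):
        g = small_repeat_genome(6, length=1200)
        k = 3
        got = repetitive_kmers(g, 8, k)
        text = g.concat
        for kmer, pos in got.items():
            assert list(pos) == naive_occurrences(text, kmer)
            assert len(pos) > k

    def test_index_save_load_roundtrip(self, tmp_path, demo_index):
        p = tmp_path / "demo.idx"
        demo_index.save(str(p))
        from mam.local_index import MAMIndex

        back = MAMIndex.load(str(p))
        assert back.l_init == demo_index.l_init
        assert set(back.roots) == set(demo_index.roots)
        bad = tmp_path / "bad.idx"
        bad.write_bytes(b"not an index")
        with pytest.raises(ValueError):
            MAMIndex.load(str(bad))
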