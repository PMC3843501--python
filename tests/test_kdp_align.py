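import math

import numpy as np
import pytest
from Bio import Align
from Bio.Align import substitution_matrices

from kclust.seqio import SequenceRecord, encode
from kclust.kmer_engine import KmerSpec
from kclust.kdp_align import (
    GAP_EXTEND,
    GAP_OPEN,
    KdpAlignment,
    MatchAnchor,
    alignment_stats,
    brute_force_chain,
    chain_matches,
    collect_matches,
    constrained_alignment,
    kdp_align,
    merge_colinear,
)
from kclust.synthetic import mutate_to_identity, random_sequence


@pytest.fixture(scope="module")
def sw_aligner():
    """Independent unconstrained local Smith-Waterman (Biopython)."""
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -(GAP_OPEN + GAP_EXTEND)
    aligner.extend_gap_score = -GAP_EXTEND
    return aligner


def _pair(rng, length, identity):
    s = random_sequence(length, seed=int(rng.integers(2**31)), seq_id="t")
    m = mutate_to_identity(s, identity, seed=int(rng.integers(2**31)), seq_id="q")
    return encode(m), encode(s), m, s


class TestCollectMatches:
    def test_identical_sequences_diagonal(self, scoring):
        seq = encode(random_sequence(30, seed=1))
        spec = KmerSpec("1111", 4)
        anchors = collect_matches(seq, seq, spec, scoring)
        diagonal = [a for a in anchors if a.qpos == a.tpos]
        assert len(diagonal) == 30 - 3
        assert all(a.score >= 4 for a in anchors)

    def test_no_matches_above_threshold(self, scoring):
        a = encode(SequenceRecord("a", "a", "AAAAAAAAAA"))
        b = encode(SequenceRecord("b", "b", "WWWWWWWWWW"))
        spec = KmerSpec("1111", 10)
        assert collect_matches(a, b, spec, scoring) == []

    def test_anchor_count_matches_chance_rate(self, scoring, rng):
        """For unrelated sequences the expected anchor count is about
        p_match * L_q * L_t with p_match = mean list length / 20**4."""
        spec = KmerSpec("1111", 13)
        total = 0
        n_win = 0
        reps = 12
        list_len_total = 0
        for i in range(reps):
            q = encode(random_sequence(120, seed=1000 + i, seq_id="q"))
            t = encode(random_sequence(120, seed=2000 + i, seq_id="t"))
            anchors = collect_matches(q, t, spec, scoring)
            total += len(anchors)
            n_win += (120 - 3) ** 2
        from kclust.kmer_engine import count_similar_kmers, sample_background_kmers

        sample = sample_background_kmers(4, 400, scoring, seed=5)
        r = np.mean([count_similar_kmers(k, 4, 13, scoring) for k in sample])
        expected = r / 20**4
        observed = total / n_win
        assert observed == pytest.approx(expected, rel=0.35)


class TestChainMatches:
    def test_single_anchor(self):
        a = MatchAnchor(3, 5, 17, (0, 1, 2, 3))
        chain, score = chain_matches([a])
        assert chain == [a] and score == 17

    def test_two_colinear_anchors_no_gap_cost(self):
        a = MatchAnchor(0, 0, 10, (0, 1, 2, 3))
        b = MatchAnchor(10, 10, 12, (0, 1, 2, 3))
        chain, score = chain_matches([a, b])
        assert score == 22 and len(chain) == 2

    def test_diagonal_shift_pays_gap(self):
        a = MatchAnchor(0, 0, 10, (0, 1, 2, 3))
        b = MatchAnchor(10, 13, 12, (0, 1, 2, 3))
        _, score = chain_matches([a, b], gap_open=5, gap_extend=1)
        assert score == 10 + 12 - (5 + 3)

    def test_empty_input(self):
        assert chain_matches([]) == ([], 0.0)

    def test_unprofitable_join_skipped(self):
        a = MatchAnchor(0, 0, 10, (0, 1, 2, 3))
        b = MatchAnchor(10, 40, 3, (0, 1, 2, 3))  # far off-diagonal
        chain, score = chain_matches([a, b], gap_open=22, gap_extend=2)
        assert chain == [a] and score == 10

    @pytest.mark.parametrize("trial", range(8))
    def test_equals_exhaustive_subset_search(self, rng, trial):
        n = int(rng.integers(2, 11))
        anchors = []
        for _ in range(n):
            q, t = int(rng.integers(0, 60)), int(rng.integers(0, 60))
            anchors.append(MatchAnchor(q, t, int(rng.integers(4, 30)), (0, 1, 2, 3)))
        _, got = chain_matches(anchors, gap_open=11, gap_extend=1)
        want = brute_force_chain(anchors, gap_open=11, gap_extend=1)
        assert got == pytest.approx(want)


class TestMergeColinear:
    def test_overlapping_same_diagonal_counted_once(self, scoring):
        seq = encode(random_sequence(20, seed=3))
        spec = KmerSpec("1111", 4)
        anchors = collect_matches(seq, seq, spec, scoring)
        runs = merge_colinear(anchors, seq, seq, scoring)
        main = [r for r in runs if r.qpos == 0 and r.tpos == 0]
        assert len(main) == 1
        # the merged run scores each residue pair exactly once
        assert main[0].score == int(scoring.matrix[seq.codes, seq.codes].sum())
        assert main[0].offsets == tuple(range(20))

    def test_distinct_diagonals_untouched(self, scoring):
        a = encode(SequenceRecord("a", "a", "ACDEFGHIKLMNPQRSTVWY"))
        anchors = [MatchAnchor(0, 0, 10, (0, 1, 2, 3)), MatchAnchor(8, 9, 11, (0, 1, 2, 3))]
        runs = merge_colinear(anchors, a, a, scoring)
        assert len(runs) == 2


class TestConstrainedAlignment:
    def test_identical_sequences_equal_smith_waterman(self, scoring, sw_aligner):
        rec = random_sequence(80, seed=7)
        e = encode(rec)
        aln = kdp_align(e, e, KmerSpec.spaced_4mer(), scoring, db_size=1000)
        assert aln.raw_score == int(sw_aligner.score(rec.residues, rec.residues))
        assert aln.identity == 1.0
        assert aln.target_coverage == 1.0
        assert aln.pairs == [(i, i) for i in range(80)]

    @pytest.mark.parametrize("identity", [0.3, 0.5, 0.8])
    def test_never_exceeds_smith_waterman(self, scoring, sw_aligner, rng, identity):
        for _ in range(3):
            q, t, qrec, trec = _pair(rng, 150, identity)
            aln = kdp_align(q, t, KmerSpec.spaced_4mer(), scoring, db_size=10**5)
            sw = sw_aligner.score(qrec.residues, trec.residues)
            assert aln.raw_score <= sw + 1e-9

    def test_often_equals_smith_waterman_on_close_homologs(self, scoring, sw_aligner, rng):
        """When the chain anchors lie on the optimal path the corridor DP
        recovers the exact unconstrained optimum."""
        equal = 0
        trials = 6
        for _ in range(trials):
            q, t, qrec, trec = _pair(rng, 150, 0.7)
            aln = kdp_align(q, t, KmerSpec.spaced_4mer(), scoring, db_size=10**5)
            if aln.raw_score == int(sw_aligner.score(qrec.residues, trec.residues)):
                equal += 1
        assert equal >= trials - 1

    def test_empty_chain_gives_empty_alignment(self, scoring):
        a = encode(SequenceRecord("a", "a", "AAAAAAAAAAAA"))
        b = encode(SequenceRecord("b", "b", "WWWWWWWWWWWW"))
        aln = kdp_align(a, b, KmerSpec("1111", 10), scoring)
        assert aln.pairs == [] and aln.raw_score == 0 and not aln

    def test_corridor_cells_bounded_by_full_matrix(self, scoring, rng):
        """Work is restricted to corridors between anchors: their total
        area never exceeds the full DP matrix."""
        q, t, *_ = _pair(rng, 200, 0.5)
        anchors = collect_matches(q, t, KmerSpec.spaced_4mer(), scoring)
        runs = merge_colinear(anchors, q, t, scoring)
        chain, _ = chain_matches(runs)
        assert chain
        cpairs = [(a.qpos + o, a.tpos + o) for a in chain for o in a.offsets]
        area = 0
        for (i0, j0), (i1, j1) in zip(cpairs, cpairs[1:]):
            area += (i1 - i0) * (j1 - j0)
        area += cpairs[0][0] * cpairs[0][1]
        area += (len(q) - cpairs[-1][0]) * (len(t) - cpairs[-1][1])
        assert area <= len(q) * len(t)


class TestAlignmentStats:
    def _stub(self, pairs, raw, q, t):
        return alignment_stats(
            KdpAlignment("q", "t", [], pairs, raw), q, t, db_size=1000
        )

    def test_coverage_ratio(self, scoring):
        q = encode(SequenceRecord("q", "q", "A" * 50))
        t = encode(SequenceRecord("t", "t", "A" * 50))
        pairs = [(i, i + 5) for i in range(40)]  # touches target residues 5..44
        aln = self._stub(pairs, 160, q, t)
        assert aln.target_coverage == pytest.approx(0.8)
        assert aln.identity == 1.0
        assert aln.score_per_column == pytest.approx(160 / 40)

    def test_gap_columns_counted(self, scoring):
        q = encode(SequenceRecord("q", "q", "ACDEFGHIKL"))
        t = encode(SequenceRecord("t", "t", "ACDEFGHIKL"))
        pairs = [(0, 0), (1, 1), (4, 2)]  # two query residues skipped
        aln = self._stub(pairs, 30, q, t)
        assert aln.n_columns == 5
        assert aln.score_per_column == pytest.approx(6.0)

    def test_evalue_decreases_with_score(self, scoring):
        q = encode(SequenceRecord("q", "q", "A" * 30))
        t = encode(SequenceRecord("t", "t", "A" * 30))
        pairs = [(i, i) for i in range(30)]
        e1 = self._stub(pairs, 50, q, t).e_value
        e2 = self._stub(pairs, 100, q, t).e_value
        assert e2 < e1

    def test_identity_symmetric_under_transposition(self, scoring, rng):
        q, t, *_ = _pair(rng, 100, 0.5)
        aln = kdp_align(q, t, KmerSpec.spaced_4mer(), scoring, db_size=1000)
        flipped = KdpAlignment("t", "q", [], [(j, i) for i, j in aln.pairs], aln.raw_score)
        alignment_stats(flipped, t, q, db_size=1000)
        assert flipped.identity == pytest.approx(aln.identity)

    def test_empty_alignment_rejected(self, scoring):
        q = encode(SequenceRecord("q", "q", "AAA"))
        with pytest.raises(ValueError):
            alignment_stats(KdpAlignment("q", "q", [], [], 0), q, q, 10)
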