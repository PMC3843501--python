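import numpy as np
import pytest

from kclust.seqio import AMINO_ACIDS, SequenceRecord, encode
from kclust.kmer_engine import KmerSpec
from kclust.kdp_align import kdp_align
from kclust.greedy_cluster import Cluster, ClusterParams, Clustering, cluster
from kclust.prefilter import IndexTable
from kclust.profile_cluster import (
    build_msa,
    build_profile,
    consensus,
    iterate,
    msa_to_fasta,
)
from kclust.synthetic import FamilySpec, make_family, random_sequence

I_CODE, L_CODE, W_CODE = (AMINO_ACIDS.index(c) for c in "ILW")


def _cluster_of(records, scoring, spec4=None, db_size=10**5):
    """Build a Cluster with real member alignments to the first record."""
    spec4 = spec4 or KmerSpec.spaced_4mer()
    rep = records[0]
    rep_enc = encode(rep)
    members = []
    for rec in records[1:]:
        aln = kdp_align(encode(rec), rep_enc, spec4, scoring, db_size=db_size)
        members.append((rec, aln))
    return Cluster(representative=rep, members=members, creation_order=0)


class TestBuildMsa:
    def test_singleton(self, scoring):
        rep = random_sequence(40, seed=1, seq_id="r")
        msa = build_msa(Cluster(representative=rep))
        assert msa.n_sequences == 1
        assert msa.rows[0].tolist() == encode(rep).codes.tolist()

    def test_identical_duplicates_are_gapless(self, scoring):
        rep = random_sequence(50, seed=2, seq_id="r")
        dup = SequenceRecord("d", "d", rep.residues)
        msa = build_msa(_cluster_of([rep, dup], scoring))
        assert (msa.rows >= 0).all()
        assert (msa.rows[1] == msa.rows[0]).all()

    def test_partial_member_has_end_gaps(self, scoring):
        rep = random_sequence(80, seed=3, seq_id="r")
        frag = SequenceRecord("f", "f", rep.residues[10:60])
        msa = build_msa(_cluster_of([rep, frag], scoring))
        row = msa.rows[1]
        assert (row[:10] == -1).all() and (row[60:] == -1).all()
        assert (row[10:60] >= 0).all()


class TestConsensus:
    def test_identical_rows_reproduce_sequence(self, scoring):
        rep = random_sequence(30, seed=5, seq_id="r")
        dup = SequenceRecord("d", "d", rep.residues)
        cons = consensus(build_msa(_cluster_of([rep, dup], scoring)), scoring)
        assert cons.codes.tolist() == encode(rep).codes.tolist()

    def test_pure_column(self, scoring):
        msa = build_msa(Cluster(representative=SequenceRecord("r", "r", "AAAA")))
        cons = consensus(msa, scoring)
        assert cons.codes.tolist() == [0, 0, 0, 0]

    def test_mixed_column_maximizes_expected_score(self, scoring):
        # column half I / half L: best residue by expected BLOSUM62 score
        freqs = np.zeros(20)
        freqs[I_CODE] = freqs[L_CODE] = 0.5
        expected = (freqs[None, :] @ scoring.matrix[:20, :20].T).ravel()
        best = int(expected.argmax())
        rep = SequenceRecord("r", "r", "I")
        other = SequenceRecord("o", "o", "L")
        from kclust.kdp_align import KdpAlignment

        aln = KdpAlignment("o", "r", [], [(0, 0)], 4)
        cl = Cluster(representative=rep, members=[(other, aln)])
        cons = consensus(build_msa(cl), scoring)
        assert cons.codes.tolist() == [best]


class TestBuildProfile:
    def test_pure_prior_recovers_matrix_rows(self, scoring):
        """With admixture 1 a single-sequence profile is exactly the
        substitution-matrix rows of its residues."""
        rep = random_sequence(25, seed=6, seq_id="r")
        msa = build_msa(Cluster(representative=rep))
        prof = build_profile(msa, scoring, tau=1.0)
        expected = scoring.matrix[encode(rep).codes][:, :20]
        assert (prof.scores[:, :20] == expected).all()

    def test_conserved_column_dominates(self, scoring):
        msa = build_msa(Cluster(representative=SequenceRecord("r", "r", "WWW")))
        prof = build_profile(msa, scoring)
        col = prof.scores[0, :20]
        assert col[W_CODE] == col.max()
        assert (np.delete(col, W_CODE) < col[W_CODE]).all()

    def test_matches_direct_log_odds(self, scoring):
        """Profile scores equal an independent evaluation of the mixed
        log-odds formula."""
        rep = random_sequence(40, seed=8, seq_id="r")
        member = SequenceRecord("m", "m", rep.residues[:35])
        cl = _cluster_of([rep, member], scoring)
        msa = build_msa(cl)
        tau = 0.37
        prof = build_profile(msa, scoring, tau=tau)
        S = scoring.matrix[:20, :20].astype(float)
        f = scoring.background
        for col in (0, 10, 37):
            obs = np.zeros(20)
            vals = [c for c in msa.rows[:, col] if c >= 0]
            for c in vals:
                obs[c] += 1 / len(vals)
            pseudo = np.zeros(20)
            for y in range(20):
                pseudo[y] = sum(obs[x] * f[y] * 2 ** (S[x, y] / 2) for x in range(20))
            p = (1 - tau) * obs + tau * pseudo
            expected = np.rint(2 * np.log2(np.maximum(p, 1e-30) / f)).clip(-64)
            assert (prof.scores[col, :20] == expected.astype(int)).all()

    def test_profile_mode_reduces_to_sequence_mode(self, scoring, spec6):
        """tau=1 singleton profiles give exactly the sequence-mode
        prefilter scores."""
        reps = [random_sequence(70, seed=20 + i, seq_id=f"r{i}") for i in range(4)]
        query = random_sequence(70, seed=30, seq_id="q")
        table = IndexTable(spec6, scoring)
        for r in reps:
            table.add(encode(r))
        qenc = encode(query)
        seq_hits = [(h.seq_no, h.raw_score) for h in table.score_query(qenc, -1.0)]
        msa = build_msa(Cluster(representative=query))
        prof = build_profile(msa, scoring, tau=1.0)
        prof_hits = [
            (h.seq_no, h.raw_score)
            for h in table.score_query(qenc, -1.0, pssm=prof.scores)
        ]
        assert prof_hits == seq_hits


class TestIterate:
    def test_unrelated_singletons_unchanged(self, scoring):
        db = [random_sequence(100, seed=40 + i, seq_id=f"s{i}") for i in range(6)]
        clustering = cluster(db)
        assert len(clustering) == 6
        merged = iterate(clustering)
        assert len(merged) == 6

    def test_split_family_is_remerged(self, scoring):
        fam = make_family(FamilySpec("fam", 8, 160, 0.75, 0.85, seed=9, length_jitter=0.0))
        half_a = cluster(fam[:4])
        half_b = cluster(fam[4:])
        assert len(half_a) == 1 and len(half_b) == 1
        combined = Clustering(
            clusters=[
                half_a.clusters[0],
                Cluster(
                    representative=half_b.clusters[0].representative,
                    members=half_b.clusters[0].members,
                    creation_order=1,
                ),
            ],
            params=half_a.params,
            n_sequences=8,
            n_residues=sum(len(r.residues) for r in fam),
        )
        merged = iterate(combined)
        assert len(merged) == 1
        assert sorted(merged.all_ids()) == sorted(r.id for r in fam)

    def test_cluster_count_never_increases_and_partition_preserved(self, scoring):
        db = []
        for f in range(3):
            db += make_family(FamilySpec(f"fam{f}", 5, 140, 0.5, 0.7, seed=60 + f))
        clustering = cluster(db)
        merged = iterate(clustering)
        assert len(merged) <= len(clustering)
        assert sorted(merged.all_ids()) == sorted(r.id for r in db)
        again = iterate(merged)
        assert len(again) <= len(merged)

    def test_different_families_not_merged(self, scoring):
        from kclust.synthetic import labels_of, score_clustering

        db = []
        for f in range(3):
            db += make_family(FamilySpec(f"fam{f}", 5, 140, 0.5, 0.7, seed=80 + f))
        merged = iterate(cluster(db))
        assert score_clustering(merged, labels_of(db)).n_corrupted == 0


def test_msa_fasta_rendering(scoring):
    rep = random_sequence(30, seed=90, seq_id="r")
    frag = SequenceRecord("f", "f", rep.residues[5:25])
    text = msa_to_fasta(build_msa(_cluster_of([rep, frag], scoring)))
    lines = text.strip().splitlines()
    assert lines[0] == ">r"
    assert lines[1] == rep.residues
    assert lines[3] == "-" * 5 + rep.residues[5:25] + "-" * 5
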