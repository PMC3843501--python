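"""Profile-based second clustering iteration.

Each first-iteration cluster is summarized by a star multiple sequence
alignment (every member placed onto the representative's columns via its
stored pairwise alignment), a consensus sequence, and a position-specific
score profile.  A second greedy pass then treats each cluster as a query:
its consensus drives spaced k-mer extraction while similarity scores are
read from the profile columns instead of the substitution matrix, in both
the prefilter and the anchor aligner.  Clusters accepted against an
already-created merged cluster are merged; the pass can only reduce the
cluster count and never moves a sequence out of its cluster.

Profiles use matrix-derived pseudocounts: the observed gap-excluded
column frequencies are mixed with the substitution-matrix conditional
distribution of the column, with mixing weight decreasing in the number
of member sequences.  With admixture 1 (pure prior) a single-sequence
column reproduces the matrix row of its residue exactly, which makes
profile mode reduce to sequence mode on singleton clusters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .greedy_cluster import Cluster, ClusterLog, ClusterParams, Clustering, accept
from .kmer_engine import ScoringModel
from .kdp_align import kdp_align
from .prefilter import IndexTable
from .seqio import EncodedSequence, decode_codes, encode

#: Pseudocount admixture at member count 1; the effective admixture is
#: tau0 / (1 + member_count / 10).
TAU0 = 1.0

_GAP = -1


@dataclass
class ClusterMsa:
    """Star MSA on the representative's columns.

    ``rows[0]`` is the representative (ungapped); other rows hold member
    residue codes aligned to representative columns, with -1 for gaps.
    Member insertions relative to the representative are excluded.
    """

    ids: list[str]
    rows: np.ndarray  # (n_sequences, L_rep) int, -1 = gap

    @property
    def n_sequences(self) -> int:
        return int(self.rows.shape[0])

    @property
    def n_columns(self) -> int:
        return int(self.rows.shape[1])


@dataclass
class Profile:
    """Per-column position-specific scores (half-bits) plus consensus."""

    scores: np.ndarray  # (L, 21) int, wildcard column = 0
    consensus: EncodedSequence
    member_count: int


def build_msa(cluster: Cluster) -> ClusterMsa:
    """Star MSA from the members' stored alignments to the representative.

    Each stored alignment has the member as query and the representative
    as target, so target indices are column indices directly."""
    rep = encode(cluster.representative)
    L = len(rep)
    rows = [rep.codes]
    ids = [rep.id]
    for member, aln in cluster.members:
        row = np.full(L, _GAP, dtype=np.int64)
        if aln is not None:
            mem = encode(member)
            for qi, tj in aln.pairs:
                row[tj] = mem.codes[qi]
        rows.append(row)
        ids.append(member.id)
    return ClusterMsa(ids=ids, rows=np.vstack(rows))


def _column_frequencies(msa: ClusterMsa) -> np.ndarray:
    """Gap-excluded observed frequencies, (L, 20); all-gap columns are
    left at zero."""
    L = msa.n_columns
    freqs = np.zeros((L, 20))
    for a in range(20):
        freqs[:, a] = (msa.rows == a).sum(axis=0)
    totals = freqs.sum(axis=1, keepdims=True)
    nonzero = totals[:, 0] > 0
    freqs[nonzero] /= totals[nonzero]
    return freqs


def consensus(msa: ClusterMsa, scoring: ScoringModel) -> EncodedSequence:
    """Per column, the residue x maximizing sum_a f_a * S(x, a); ties go
    to the lower code; all-gap columns take the representative residue."""
    freqs = _column_frequencies(msa)
    S = scoring.matrix[:20, :20]
    expected = freqs @ S.T  # (L, 20): expected score of each candidate x
    cons = expected.argmax(axis=1)
    all_gap = freqs.sum(axis=1) == 0
    cons[all_gap] = msa.rows[0][all_gap]
    return EncodedSequence(id=msa.ids[0] + "_consensus", codes=cons.astype(np.int64))


def build_profile(
    msa: ClusterMsa,
    scoring: ScoringModel,
    tau: float | None = None,
    min_score: int = -64,
) -> Profile:
    """Position-specific half-bit scores 2*log2(p_col(y) / f_y).

    ``p_col`` mixes observed column frequencies with the matrix-derived
    pseudocount distribution of the column, sum_x f_col(x) * f_y *
    2**(S(x,y)/2), using admixture ``tau`` (default: the member-count
    schedule tau0 / (1 + m/10)).  With ``tau=1`` a single-sequence column
    yields exactly the matrix row of its residue.
    """
    m = msa.n_sequences
    if tau is None:
        tau = TAU0 / (1.0 + m / 10.0)
    freqs = _column_frequencies(msa)
    all_gap = freqs.sum(axis=1) == 0
    if all_gap.any():
        freqs[all_gap, msa.rows[0][all_gap]] = 1.0
    f = scoring.background
    S = scoring.matrix[:20, :20].astype(float)
    # pseudo[l, y] = sum_x freqs[l, x] * f_y * 2**(S(x, y)/2)
    pseudo = freqs @ (f[None, :] * np.exp2(S / 2.0))
    p = (1.0 - tau) * freqs + tau * pseudo
    with np.errstate(divide="ignore"):
        scores = 2.0 * np.log2(np.maximum(p, 1e-30) / f[None, :])
    scores = np.clip(np.rint(scores), min_score, None).astype(np.int64)
    L = msa.n_columns
    full = np.zeros((L, 21), dtype=np.int64)
    full[:, :20] = scores
    cons = consensus(msa, scoring)
    return Profile(scores=full, consensus=cons, member_count=m)


def summarize_cluster(cluster: Cluster, scoring: ScoringModel) -> Profile:
    return build_profile(build_msa(cluster), scoring)


def iterate(
    clustering: Clustering,
    params: ClusterParams | None = None,
    scoring: ScoringModel | None = None,
    log: ClusterLog | None = None,
) -> Clustering:
    """Greedy profile-vs-consensus merging pass.

    Clusters (sorted by consensus length, descending) are queried with
    their profiles against the consensus sequences of already-created
    merged clusters; an accepted match merges the member sets.  The
    partition of input sequences is preserved and the cluster count never
    increases.
    """
    params = params or clustering.params
    scoring = scoring or ScoringModel.blosum62()
    log = log if log is not None else ClusterLog()
    profiles = [summarize_cluster(cl, scoring) for cl in clustering.clusters]
    order = sorted(
        range(len(profiles)),
        key=lambda i: (-len(profiles[i].consensus), clustering.clusters[i].creation_order),
    )
    total_cons_residues = sum(len(p.consensus) for p in profiles)
    table = IndexTable(params.spec6, scoring)
    founders: list[int] = []  # cluster index per indexed consensus
    merged_members: dict[int, list[int]] = {}  # founder -> absorbed cluster indices
    for i in order:
        log.queries += 1
        prof = profiles[i]
        cons = prof.consensus
        assigned = False
        hits = table.score_query(cons, params.prefilter_threshold, pssm=prof.scores)
        log.prefilter_hits += len(hits)
        if params.max_candidates is not None:
            hits = hits[: params.max_candidates]
        for hit in hits:
            founder_idx = founders[hit.seq_no]
            target_cons = profiles[founder_idx].consensus
            aln = kdp_align(
                cons,
                target_cons,
                params.spec4,
                scoring,
                db_size=total_cons_residues,
                gap_open=params.gap_open,
                gap_extend=params.gap_extend,
                pssm=prof.scores,
            )
            log.alignments += 1
            if aln.pairs and accept(aln, params):
                merged_members[founder_idx].append(i)
                log.acceptances += 1
                assigned = True
                break
        if not assigned:
            table.add(cons)
            founders.append(i)
            merged_members[i] = []
    new_clusters: list[Cluster] = []
    for rank, founder_idx in enumerate(founders):
        base = clustering.clusters[founder_idx]
        members = list(base.members)
        for absorbed_idx in merged_members[founder_idx]:
            absorbed = clustering.clusters[absorbed_idx]
            members.append((absorbed.representative, None))
            members.extend((m, None) for m, _a in absorbed.members)
        new_clusters.append(
            Cluster(representative=base.representative, members=members, creation_order=rank)
        )
    return Clustering(new_clusters, params, clustering.n_sequences, clustering.n_residues)


def msa_to_fasta(msa: ClusterMsa) -> str:
    """Aligned-FASTA rendering of a star MSA ('-' for gaps)."""
    out = []
    for sid, row in zip(msa.ids, msa.rows):
        seq = "".join("-" if c == _GAP else decode_codes([c]) for c in row)
        out.append(f">{sid}\n{seq}\n")
    return "".join(out)
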