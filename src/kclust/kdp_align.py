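"""Two-stage anchor alignment (k-mer dynamic programming).

Stage one finds all pairs of similar spaced 4-mers between query and
target (via similar-4-mer lists looked up in a small index of the target,
never by all-pairs scoring) and chains them by dynamic programming into
the highest-scoring local anchor chain: the sum of anchor scores minus
affine gap costs between anchors on different diagonals.  Stage two
computes the optimal residue-level local alignment constrained to pass
through every matched position of the chained anchors, by affine-gap
dynamic programming restricted to the rectangular corridors between
consecutive constrained pairs plus free local extensions before the first
and after the last anchor.

Scores are integer half-bits throughout.  The resulting alignment carries
the statistics used as clustering acceptance criteria: score per aligned
column, sequence identity, target coverage, and a Karlin-Altschul style
E-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .kmer_engine import KmerSpec, ScoringModel, extract_spaced_kmers, kmer_code, similar_kmers_from_rows
from .seqio import EncodedSequence

#: Affine gap penalties in half-bits (a gap of length g costs
#: gap_open + gap_extend * g), the half-bit analogue of BLAST's 11/1.
GAP_OPEN = 22
GAP_EXTEND = 2

#: Karlin-Altschul parameters for gapped BLOSUM62 statistics.
LAMBDA = 0.267
K_PARAM = 0.041

_HALFBIT_TO_NAT = math.log(2.0) / 2.0


@dataclass
class MatchAnchor:
    """A similar spaced-4-mer match (or a merged colinear run of them).

    ``offsets`` are the matched positions relative to (qpos, tpos); for a
    single anchor they are the pattern's match offsets.
    """

    qpos: int
    tpos: int
    score: int
    offsets: tuple[int, ...]

    @property
    def diagonal(self) -> int:
        return self.qpos - self.tpos

    @property
    def qend(self) -> int:
        return self.qpos + self.offsets[-1]

    @property
    def tend(self) -> int:
        return self.tpos + self.offsets[-1]


@dataclass
class KdpAlignment:
    """Anchor chain plus refined residue alignment and its statistics."""

    query_id: str
    target_id: str
    chain: list[MatchAnchor]
    pairs: list[tuple[int, int]]  # aligned (query index, target index)
    raw_score: int  # half-bits
    n_columns: int = 0  # aligned pairs + gapped columns
    score_per_column: float = 0.0
    identity: float = 0.0
    target_coverage: float = 0.0
    e_value: float = math.inf

    def __bool__(self) -> bool:
        return bool(self.pairs)


def _query_rows(query: EncodedSequence, scoring: ScoringModel, pssm: np.ndarray | None) -> np.ndarray:
    return pssm if pssm is not None else scoring.rows_for(query.codes)


def collect_matches(
    query: EncodedSequence,
    target: EncodedSequence,
    spec4: KmerSpec,
    scoring: ScoringModel,
    pssm: np.ndarray | None = None,
) -> list[MatchAnchor]:
    """All (query window, target window) pairs whose spaced 4-mers score
    >= ``spec4.s_min_total``."""
    target_index: dict[int, list[int]] = {}
    for tpos, tw in extract_spaced_kmers(target, spec4):
        target_index.setdefault(kmer_code(tw), []).append(tpos)
    offs = tuple(int(o) for o in spec4.offsets)
    anchors: list[MatchAnchor] = []
    for qpos, qw in extract_spaced_kmers(query, spec4):
        if pssm is None:
            rows = scoring.rows_for(qw)
            dimer_lists = [
                scoring.sorted_dimer_list(int(qw[j]), int(qw[j + 1]))
                for j in range(0, spec4.k - 1, 2)
            ]
        else:
            rows = pssm[qpos + spec4.offsets]
            dimer_lists = None
        sim = similar_kmers_from_rows(
            kmer_code(qw), rows, spec4.s_min_total, dimer_lists=dimer_lists
        )
        for code, score in zip(sim.codes.tolist(), sim.scores.tolist()):
            for tpos in target_index.get(code, ()):
                anchors.append(MatchAnchor(qpos, tpos, int(score), offs))
    anchors.sort(key=lambda a: (a.qpos, a.tpos))
    return anchors


def merge_colinear(
    anchors: list[MatchAnchor],
    query: EncodedSequence,
    target: EncodedSequence,
    scoring: ScoringModel,
    pssm: np.ndarray | None = None,
) -> list[MatchAnchor]:
    """Merge overlapping same-diagonal anchors into runs.

    A run's matched offsets are the union of its anchors' offsets and its
    score is recomputed over that union, so no residue pair contributes
    twice to a chain score."""
    rows = _query_rows(query, scoring, pssm)
    by_diag: dict[int, list[MatchAnchor]] = {}
    for a in anchors:
        by_diag.setdefault(a.diagonal, []).append(a)
    merged: list[MatchAnchor] = []
    for diag, group in by_diag.items():
        group.sort(key=lambda a: a.qpos)
        cur_positions: set[int] = set()
        cur_members: list[MatchAnchor] = []
        for a in group:
            if cur_members and a.qpos <= cur_members[-1].qend:
                cur_positions.update(a.qpos + o for o in a.offsets)
                cur_members.append(a)
            else:
                if cur_members:
                    merged.append(_make_run(cur_positions, diag, rows, target))
                cur_positions = {a.qpos + o for o in a.offsets}
                cur_members = [a]
        if cur_members:
            merged.append(_make_run(cur_positions, diag, rows, target))
    merged.sort(key=lambda a: (a.qpos, a.tpos))
    return merged


def _make_run(positions: set[int], diag: int, rows: np.ndarray, target: EncodedSequence) -> MatchAnchor:
    qpos_list = sorted(positions)
    q0 = qpos_list[0]
    score = int(sum(rows[q, target.codes[q - diag]] for q in qpos_list))
    return MatchAnchor(q0, q0 - diag, score, tuple(q - q0 for q in qpos_list))


def _gap_cost(a: MatchAnchor, b: MatchAnchor, gap_open: float, gap_extend: float) -> float:
    d = abs(b.diagonal - a.diagonal)
    return 0.0 if d == 0 else gap_open + gap_extend * d


def chain_matches(
    anchors: list[MatchAnchor],
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> tuple[list[MatchAnchor], float]:
    """Best local chain of anchors, strictly increasing in both
    coordinates, maximizing sum of anchor scores minus gap costs.

    Colinear non-overlapping neighbours cost nothing; a diagonal change of
    d costs gap_open + gap_extend * d.  The empty chain (score 0) is
    allowed.  Ties are broken toward fewer anchors, then toward the chain
    with the smaller start position.
    """
    n = len(anchors)
    order = sorted(range(n), key=lambda i: (anchors[i].qpos, anchors[i].tpos))
    # per chain-end: (score, anchor count, start qpos, predecessor)
    best: list[tuple[float, int, int, int | None]] = [None] * n  # type: ignore
    for oi, i in enumerate(order):
        ai = anchors[i]
        cur = (float(ai.score), 1, ai.qpos, None)
        for j in order[:oi]:
            aj = anchors[j]
            if aj.qend < ai.qpos and aj.tend < ai.tpos:
                sj, cj, startj, _ = best[j]
                cand = (sj - _gap_cost(aj, ai, gap_open, gap_extend) + ai.score,
                        cj + 1, startj, j)
                if (cand[0], -cand[1], -cand[2]) > (cur[0], -cur[1], -cur[2]):
                    cur = cand
        best[i] = cur
    top: tuple[float, int, int, int | None] | None = None
    top_i = None
    for i in order:
        s, c, st, _ = best[i]
        if s <= 0:
            continue
        if top is None or (s, -c, -st) > (top[0], -top[1], -top[2]):
            top = best[i]
            top_i = i
    if top is None:
        return [], 0.0
    chain = []
    i = top_i
    while i is not None:
        chain.append(anchors[i])
        i = best[i][3]
    chain.reverse()
    return chain, top[0]


def brute_force_chain(
    anchors: list[MatchAnchor],
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
) -> float:
    """Exhaustive chain search over all increasing subsets (oracle for
    small anchor sets)."""
    n = len(anchors)
    if n > 16:
        raise ValueError("exhaustive search limited to 16 anchors")
    best = 0.0
    order = sorted(range(n), key=lambda i: (anchors[i].qpos, anchors[i].tpos))
    for mask in range(1, 1 << n):
        subset = [anchors[order[i]] for i in range(n) if mask >> i & 1]
        ok = all(
            a.qend < b.qpos and a.tend < b.tpos
            for a, b in zip(subset, subset[1:])
        )
        if not ok:
            continue
        score = sum(a.score for a in subset) - sum(
            _gap_cost(a, b, gap_open, gap_extend) for a, b in zip(subset, subset[1:])
        )
        best = max(best, score)
    return best


_NEG = -(10**9)


def _affine_fill(sub: np.ndarray, gap_open: float, gap_extend: float):
    """Fill affine-gap DP matrices for a corridor anchored at its origin
    corner (the preceding constrained pair).  State M[i, j]: path ends in
    a match consuming i query / j target residues beyond the anchor; E/F:
    path ends in a gap consuming a query / target residue."""
    nq, nt = sub.shape
    M = np.full((nq + 1, nt + 1), _NEG, dtype=np.float64)
    E = np.full((nq + 1, nt + 1), _NEG, dtype=np.float64)
    F = np.full((nq + 1, nt + 1), _NEG, dtype=np.float64)
    M[0, 0] = 0.0
    for i in range(1, nq + 1):
        E[i, 0] = -(gap_open + gap_extend * i)
    for j in range(1, nt + 1):
        F[0, j] = -(gap_open + gap_extend * j)
    oe = gap_open + gap_extend
    for i in range(1, nq + 1):
        Mi, Mi1, Ei, Ei1, Fi, Fi1 = M[i], M[i - 1], E[i], E[i - 1], F[i], F[i - 1]
        row = sub[i - 1]
        for j in range(1, nt + 1):
            Ei[j] = max(Mi1[j] - oe, Ei1[j] - gap_extend)
            Fi[j] = max(Mi[j - 1] - oe, Fi[j - 1] - gap_extend)
            Mi[j] = row[j - 1] + max(Mi1[j - 1], Ei1[j - 1], Fi1[j - 1])
    return M, E, F


def _traceback(M, E, F, sub, end, gap_open, gap_extend):
    """Recover the aligned (i, j) consumed-count pairs of the optimal path
    ending in state M at ``end`` and starting at the (0, 0) corner."""
    i, j = end
    pairs = []
    state = "M"
    oe = gap_open + gap_extend
    while not (i == 0 and j == 0):
        if state == "M":
            pairs.append((i, j))
            base = M[i, j] - sub[i - 1, j - 1]
            i -= 1
            j -= 1
            if i == 0 and j == 0:
                break
            if math.isclose(base, M[i, j]):
                state = "M"
            elif math.isclose(base, E[i, j]):
                state = "E"
            else:
                state = "F"
        elif state == "E":
            val = E[i, j]
            i -= 1
            state = "M" if math.isclose(val, M[i, j] - oe) else "E"
        else:
            val = F[i, j]
            j -= 1
            state = "M" if math.isclose(val, M[i, j] - oe) else "F"
    pairs.reverse()
    return pairs


def _anchored_extension(sub: np.ndarray, gap_open: float, gap_extend: float):
    """Best local extension anchored at the corner just outside ``sub``.

    ``sub[i-1, j-1]`` is the match score of consuming residues i and j
    beyond the anchor pair.  The path starts adjacent to the anchor, may
    end anywhere in a match state, and the empty extension scores 0.
    Returns (score, pairs) with pairs as 1-based consumed counts.
    """
    nq, nt = sub.shape
    if nq == 0 or nt == 0:
        return 0.0, []
    M, E, F = _affine_fill(sub, gap_open, gap_extend)
    inner = M[1:, 1:]
    best = float(inner.max(initial=0.0))
    if best <= 0.0:
        return 0.0, []
    flat = int(inner.argmax())
    end = (flat // nt + 1, flat % nt + 1)
    pairs = _traceback(M, E, F, sub, end, gap_open, gap_extend)
    return best, pairs


def _global_segment(sub: np.ndarray, gap_open: float, gap_extend: float):
    """Optimal path between two fixed aligned pairs.

    Consumes all residues of the corridor, ending in a match at the far
    corner (the next constrained pair); the starting pair's score is not
    included.  Returns (score, pairs) with 1-based consumed counts, the
    final corner included.
    """
    nq, nt = sub.shape
    M, E, F = _affine_fill(sub, gap_open, gap_extend)
    pairs = _traceback(M, E, F, sub, (nq, nt), gap_open, gap_extend)
    return float(M[nq, nt]), pairs


def constrained_alignment(
    query: EncodedSequence,
    target: EncodedSequence,
    chain: list[MatchAnchor],
    scoring: ScoringModel,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
    pssm: np.ndarray | None = None,
) -> KdpAlignment:
    """Optimal local alignment whose path passes through every matched
    position of every chained anchor."""
    if not chain:
        return KdpAlignment(query.id, target.id, [], [], 0)
    rows = _query_rows(query, scoring, pssm)
    tcodes = target.codes
    # all constrained pairs, strictly increasing by chain construction
    cpairs: list[tuple[int, int]] = []
    for a in chain:
        for o in a.offsets:
            cpairs.append((a.qpos + o, a.tpos + o))
    score_mat = rows[:, tcodes]  # (Lq, Lt) match scores

    total = float(score_mat[cpairs[0][0], cpairs[0][1]])
    pairs: list[tuple[int, int]] = [cpairs[0]]
    for (i0, j0), (i1, j1) in zip(cpairs, cpairs[1:]):
        if i1 == i0 + 1 and j1 == j0 + 1:
            total += score_mat[i1, j1]
            pairs.append((i1, j1))
            continue
        sub = score_mat[i0 + 1 : i1 + 1, j0 + 1 : j1 + 1]
        s, seg_pairs = _global_segment(sub, gap_open, gap_extend)
        total += s
        pairs.extend((i0 + u, j0 + v) for u, v in seg_pairs)
    # local extensions outside the chain
    a0, b0 = cpairs[0]
    back_sub = score_mat[a0 - 1 :: -1, b0 - 1 :: -1] if a0 > 0 and b0 > 0 else np.empty((0, 0))
    s_back, back_pairs = _anchored_extension(back_sub, gap_open, gap_extend)
    total += s_back
    a1, b1 = cpairs[-1]
    fwd_sub = score_mat[a1 + 1 :, b1 + 1 :]
    s_fwd, fwd_pairs = _anchored_extension(fwd_sub, gap_open, gap_extend)
    total += s_fwd
    full_pairs = (
        sorted((a0 - u, b0 - v) for u, v in back_pairs)
        + pairs
        + [(a1 + u, b1 + v) for u, v in fwd_pairs]
    )
    return KdpAlignment(query.id, target.id, chain, full_pairs, int(round(total)))


def alignment_stats(
    alignment: KdpAlignment,
    query: EncodedSequence,
    target: EncodedSequence,
    db_size: int,
    lambda_: float = LAMBDA,
    k_param: float = K_PARAM,
) -> KdpAlignment:
    """Populate score-per-column, identity, target coverage and E-value.

    Columns count aligned pairs plus gapped columns between them; identity
    is the fraction of columns with equal residues; coverage is the
    fraction of target residues spanned by the alignment; the E-value is
    k_param * L_query * db_size * exp(-lambda * S) with the raw half-bit
    score S converted to nats.
    """
    pairs = alignment.pairs
    if not pairs:
        raise ValueError("cannot compute statistics of an empty alignment")
    n_gap_cols = sum(
        (i1 - i0 - 1) + (j1 - j0 - 1) for (i0, j0), (i1, j1) in zip(pairs, pairs[1:])
    )
    n_cols = len(pairs) + n_gap_cols
    ident = sum(1 for i, j in pairs if query.codes[i] == target.codes[j])
    alignment.n_columns = n_cols
    alignment.score_per_column = alignment.raw_score / n_cols
    alignment.identity = ident / n_cols
    alignment.target_coverage = (pairs[-1][1] - pairs[0][1] + 1) / len(target)
    s_nats = alignment.raw_score * _HALFBIT_TO_NAT
    alignment.e_value = k_param * len(query) * db_size * math.exp(-lambda_ * s_nats)
    return alignment


def kdp_align(
    query: EncodedSequence,
    target: EncodedSequence,
    spec4: KmerSpec,
    scoring: ScoringModel,
    db_size: int | None = None,
    gap_open: float = GAP_OPEN,
    gap_extend: float = GAP_EXTEND,
    pssm: np.ndarray | None = None,
) -> KdpAlignment:
    """Full two-stage alignment of one pair, with statistics when
    ``db_size`` (total database residues) is given."""
    anchors = collect_matches(query, target, spec4, scoring, pssm)
    runs = merge_colinear(anchors, query, target, scoring, pssm)
    chain, _ = chain_matches(runs, gap_open, gap_extend)
    aln = constrained_alignment(query, target, chain, scoring, gap_open, gap_extend, pssm)
    if db_size is not None and aln.pairs:
        alignment_stats(aln, query, target, db_size)
    return aln
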