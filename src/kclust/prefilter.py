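"""Alignment-free candidate search over an inverted k-mer index.

Representative sequences are indexed by their wildcard-free spaced 6-mers
(one bucket entry per occurrence).  A query is scored against all indexed
sequences at once: for each spaced 6-mer of the query, the similar-6-mer
list is generated and, for every occurrence of a list member in the index,
the member's similarity score is added to that sequence's accumulator.
The accumulator is reset between queries by walking the list of touched
sequences only, so per-query cost is independent of the registry size.

A sequence becomes a candidate when its summed score, divided by the query
length, reaches the per-position threshold (default 0.55 half-bits per
query position).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .kmer_engine import KmerSpec, ScoringModel, extract_spaced_kmers, kmer_code, similar_kmers_from_rows
from .seqio import WILDCARD, EncodedSequence

#: Default candidate threshold in half-bits per query position.
DEFAULT_PREFILTER_THRESHOLD = 0.55


@dataclass
class PrefilterHit:
    seq_no: int
    raw_score: int  # half-bits
    per_position_score: float  # half-bits per query position


class IndexTable:
    """Inverted index from spaced k-mer code to occurrences in the
    indexed representative sequences, with a touched-list score
    accumulator for query scoring."""

    def __init__(self, spec: KmerSpec, scoring: ScoringModel):
        self.spec = spec
        self.scoring = scoring
        self.buckets: dict[int, list[int]] = {}
        self.seq_ids: list[str] = []
        self.seq_lengths: list[int] = []
        self._scores: list[int] = []  # accumulator, one slot per sequence
        self._touched: list[int] = []
        self._is_touched: list[bool] = []
        self._id_to_no: dict[str, int] = {}

    def __len__(self) -> int:
        return len(self.seq_ids)

    @property
    def total_entries(self) -> int:
        return sum(len(b) for b in self.buckets.values())

    def add(self, rep: EncodedSequence) -> int:
        """Index a representative; returns its sequence number."""
        if rep.id in self._id_to_no:
            raise ValueError(f"sequence {rep.id!r} already indexed")
        seq_no = len(self.seq_ids)
        self.seq_ids.append(rep.id)
        self.seq_lengths.append(len(rep))
        self._scores.append(0)
        self._is_touched.append(False)
        self._id_to_no[rep.id] = seq_no
        for _pos, window in extract_spaced_kmers(rep, self.spec):
            self.buckets.setdefault(kmer_code(window), []).append(seq_no)
        return seq_no

    def reset_scores(self) -> None:
        """Zero the accumulator in O(#touched sequences)."""
        scores = self._scores
        flags = self._is_touched
        for s in self._touched:
            scores[s] = 0
            flags[s] = False
        self._touched.clear()

    def score_query(
        self,
        query: EncodedSequence,
        threshold: float = DEFAULT_PREFILTER_THRESHOLD,
        pssm: np.ndarray | None = None,
    ) -> list[PrefilterHit]:
        """Sum similar-k-mer scores of the query against every indexed
        sequence; return hits at >= ``threshold`` half-bits per query
        position, sorted by raw score descending (ties: sequence number
        ascending).

        With ``pssm`` (L x 21 integer score rows) the query is scored in
        profile mode: windows are extracted from ``query`` (the consensus)
        but similarity scores come from the profile columns.
        """
        spec = self.spec
        scoring = self.scoring
        buckets = self.buckets
        scores = self._scores
        touched = self._touched
        flags = self._is_touched
        for pos, window in extract_spaced_kmers(query, spec):
            if pssm is None:
                rows = scoring.rows_for(window)
                dimer_lists = [
                    scoring.sorted_dimer_list(int(window[j]), int(window[j + 1]))
                    for j in range(0, spec.k - 1, 2)
                ]
            else:
                rows = pssm[pos + spec.offsets]
                dimer_lists = None
            sim = similar_kmers_from_rows(
                kmer_code(window), rows, spec.s_min_total, dimer_lists=dimer_lists
            )
            for code, score in zip(sim.codes.tolist(), sim.scores.tolist()):
                bucket = buckets.get(code)
                if bucket is None:
                    continue
                for seq_no in bucket:
                    if not flags[seq_no]:
                        flags[seq_no] = True
                        touched.append(seq_no)
                    scores[seq_no] += score
        L = len(query)
        hits = []
        for seq_no in touched:
            raw = scores[seq_no]
            per_pos = raw / L
            if per_pos >= threshold:
                hits.append(PrefilterHit(seq_no, raw, per_pos))
        self.reset_scores()
        hits.sort(key=lambda h: (-h.raw_score, h.seq_no))
        return hits


def brute_force_score(
    query: EncodedSequence,
    target: EncodedSequence,
    spec: KmerSpec,
    scoring: ScoringModel,
) -> int:
    """Quadratic reference scorer: sum, over all pairs of spaced k-mer
    windows of query and target, of the pair score when it reaches
    ``spec.s_min_total``.  Used as the prefilter's independent oracle."""
    total = 0
    t_windows = extract_spaced_kmers(target, spec)
    for _qpos, qw in extract_spaced_kmers(query, spec):
        if (qw == WILDCARD).any():
            continue
        rows = scoring.rows_for(qw)
        for _tpos, tw in t_windows:
            s = int(rows[np.arange(spec.k), tw].sum())
            if s >= spec.s_min_total:
                total += s
    return total
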