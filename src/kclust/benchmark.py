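"""Desk-scale benchmark utilities built on the synthetic generators.

These drive the package's own evaluation runs: similar-list length
statistics of the 6-mer stage, and the prefilter sensitivity measured on
synthetic homologous pairs that satisfy the full three-criterion
acceptance test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .greedy_cluster import ClusterParams, accept
from .kmer_engine import (
    ScoringModel,
    count_similar_kmers,
    sample_background_kmers,
)
from .kdp_align import kdp_align
from .prefilter import IndexTable
from .seqio import SequenceRecord, encode
from .synthetic import mutate_to_identity, random_sequence


def mean_similar_list_length(
    threshold_total: float,
    k: int = 6,
    n_queries: int = 10_000,
    seed: int = 0,
    scoring: ScoringModel | None = None,
) -> float:
    """Mean similar-k-mer list length over background-composition query
    k-mers at the given total half-bit threshold."""
    scoring = scoring or ScoringModel.blosum62()
    sample = sample_background_kmers(k, n_queries, scoring, seed=seed)
    return float(np.mean([count_similar_kmers(q, k, threshold_total, scoring) for q in sample]))


@dataclass
class SensitivityResult:
    n_pairs: int
    n_accepted: int
    n_passing_prefilter: int

    @property
    def sensitivity(self) -> float:
        return self.n_passing_prefilter / self.n_accepted if self.n_accepted else float("nan")


def make_homologous_pairs(
    n_pairs: int,
    seed: int,
    length_range: tuple[int, int] = (200, 400),
    identity_range: tuple[float, float] = (0.25, 0.40),
) -> list[tuple[SequenceRecord, SequenceRecord]]:
    """(original, mutant) pairs with lengths and gapless identities drawn
    uniformly from the given ranges."""
    rng = np.random.default_rng(seed)
    pairs = []
    for i in range(n_pairs):
        L = int(rng.integers(length_range[0], length_range[1] + 1))
        ident = float(rng.uniform(*identity_range))
        rep = random_sequence(L, seed=int(rng.integers(2**31)), seq_id=f"rep{i}")
        qry = mutate_to_identity(rep, ident, seed=int(rng.integers(2**31)), seq_id=f"qry{i}")
        pairs.append((rep, qry))
    return pairs


def prefilter_sensitivity(
    n_pairs: int = 500,
    seed: int = 0,
    params: ClusterParams | None = None,
    scoring: ScoringModel | None = None,
    length_range: tuple[int, int] = (200, 400),
    identity_range: tuple[float, float] = (0.25, 0.40),
) -> SensitivityResult:
    """Fraction of homologous pairs satisfying the three acceptance
    criteria whose prefilter score reaches the per-position threshold.

    Each pair is aligned with the anchor aligner (E-values use the total
    residue count of all generated pairs as the database size); accepted
    pairs are then scored query-against-representative through the
    indexed prefilter.
    """
    params = params or ClusterParams()
    scoring = scoring or ScoringModel.blosum62()
    pairs = make_homologous_pairs(n_pairs, seed, length_range, identity_range)
    db_size = sum(len(a.residues) + len(b.residues) for a, b in pairs)
    n_accepted = 0
    n_pass = 0
    for rep, qry in pairs:
        rep_enc, qry_enc = encode(rep), encode(qry)
        aln = kdp_align(qry_enc, rep_enc, params.spec4, scoring, db_size=db_size,
                        gap_open=params.gap_open, gap_extend=params.gap_extend)
        if not aln.pairs or not accept(aln, params):
            continue
        n_accepted += 1
        table = IndexTable(params.spec6, scoring)
        table.add(rep_enc)
        if table.score_query(qry_enc, params.prefilter_threshold):
            n_pass += 1
    return SensitivityResult(n_pairs, n_accepted, n_pass)
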