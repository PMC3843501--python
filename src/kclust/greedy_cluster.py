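"""Greedy incremental clustering.

Sequences are processed in order of decreasing length.  Each query is
scored against the representatives of the already-created clusters with
the alignment-free prefilter; candidates are aligned in descending
prefilter-score order with the anchor aligner, and the query joins the
first cluster whose representative satisfies all three acceptance
criteria (score per column, E-value, representative coverage).  Otherwise
the query founds a new cluster and its spaced 6-mers are added to the
index.  Because of the length ordering, every representative is at least
as long as its members, so the coverage criterion is always evaluated on
the longer sequence of the pair.

A block-wise mode keeps only part of the database indexed at a time:
blocks of the length-sorted input are clustered one after another, each
block being first compared against the representatives of earlier blocks
(spilled to disk) before its remainder is clustered within the block.
"""

from __future__ import annotations

import math
import tempfile
from dataclasses import dataclass, field
from functools import lru_cache
from pathlib import Path

from . import seqio
from .kmer_engine import KmerSpec, ScoringModel
from .kdp_align import GAP_EXTEND, GAP_OPEN, KdpAlignment, kdp_align
from .prefilter import DEFAULT_PREFILTER_THRESHOLD, IndexTable
from .seqio import EncodedSequence, SequenceRecord, encode

#: Default acceptance thresholds.
DEFAULT_SCORE_PER_COLUMN = 1.12  # half-bits; corresponds to ~30% identity
DEFAULT_MAX_EVALUE = 1e-3
DEFAULT_MIN_COVERAGE = 0.8


@dataclass(frozen=True)
class ClusterParams:
    """Thresholds and k-mer stages of one clustering run."""

    min_score_per_column: float = DEFAULT_SCORE_PER_COLUMN
    max_evalue: float = DEFAULT_MAX_EVALUE
    min_coverage: float = DEFAULT_MIN_COVERAGE
    prefilter_threshold: float = DEFAULT_PREFILTER_THRESHOLD
    spec6: KmerSpec = field(default_factory=KmerSpec.spaced_6mer)
    spec4: KmerSpec = field(default_factory=KmerSpec.spaced_4mer)
    gap_open: float = GAP_OPEN
    gap_extend: float = GAP_EXTEND
    max_candidates: int | None = None  # optional cap on alignments per query

    def __post_init__(self):
        if not 0 < self.min_coverage <= 1:
            raise ValueError("coverage threshold must be in (0, 1]")
        if self.max_evalue <= 0:
            raise ValueError("E-value threshold must be positive")


@dataclass
class Cluster:
    representative: SequenceRecord
    members: list[tuple[SequenceRecord, KdpAlignment]] = field(default_factory=list)
    creation_order: int = 0

    @property
    def size(self) -> int:
        return 1 + len(self.members)

    def member_ids(self) -> list[str]:
        return [self.representative.id] + [m.id for m, _ in self.members]


@dataclass
class Clustering:
    clusters: list[Cluster]
    params: ClusterParams
    n_sequences: int
    n_residues: int

    def __len__(self) -> int:
        return len(self.clusters)

    def all_ids(self) -> list[str]:
        out = []
        for cl in self.clusters:
            out.extend(cl.member_ids())
        return out


def accept(alignment: KdpAlignment, params: ClusterParams) -> bool:
    """The three acceptance criteria: minimum score per column, maximum
    E-value, minimum coverage of the representative (target)."""
    return (
        alignment.score_per_column >= params.min_score_per_column
        and alignment.e_value <= params.max_evalue
        and alignment.target_coverage >= params.min_coverage
    )


@dataclass
class ClusterLog:
    """Per-stage counters of one clustering run."""

    queries: int = 0
    prefilter_hits: int = 0
    alignments: int = 0
    acceptances: int = 0


def _try_assign(
    query: EncodedSequence,
    record: SequenceRecord,
    table: IndexTable,
    clusters_by_seqno: list[Cluster],
    params: ClusterParams,
    scoring: ScoringModel,
    db_residues: int,
    log: ClusterLog,
) -> bool:
    """Prefilter, align candidates in prefilter order, join on first accept."""
    hits = table.score_query(query, params.prefilter_threshold)
    log.prefilter_hits += len(hits)
    if params.max_candidates is not None:
        hits = hits[: params.max_candidates]
    for hit in hits:
        cluster = clusters_by_seqno[hit.seq_no]
        rep_enc = encode(cluster.representative)
        aln = kdp_align(
            query,
            rep_enc,
            params.spec4,
            scoring,
            db_size=db_residues,
            gap_open=params.gap_open,
            gap_extend=params.gap_extend,
        )
        log.alignments += 1
        if aln.pairs and accept(aln, params):
            cluster.members.append((record, aln))
            log.acceptances += 1
            return True
    return False


def cluster(
    db: list[SequenceRecord],
    params: ClusterParams | None = None,
    scoring: ScoringModel | None = None,
    log: ClusterLog | None = None,
) -> Clustering:
    """Cluster a sequence database greedily; deterministic given input."""
    params = params or ClusterParams()
    scoring = scoring or ScoringModel.blosum62()
    log = log if log is not None else ClusterLog()
    _check_unique_ids(db)
    ordered = seqio.sort_by_length(db)
    db_residues = sum(len(r) for r in db)
    table = IndexTable(params.spec6, scoring)
    clusters: list[Cluster] = []
    clusters_by_seqno: list[Cluster] = []
    for record in ordered:
        log.queries += 1
        query = encode(record)
        if not _try_assign(query, record, table, clusters_by_seqno, params,
                           scoring, db_residues, log):
            cl = Cluster(representative=record, creation_order=len(clusters))
            clusters.append(cl)
            table.add(query)
            clusters_by_seqno.append(cl)
    return Clustering(clusters, params, len(db), db_residues)


def cluster_blocks(
    db: list[SequenceRecord],
    params: ClusterParams | None = None,
    block_size: int = 1000,
    scoring: ScoringModel | None = None,
    workdir: str | Path | None = None,
    log: ClusterLog | None = None,
) -> Clustering:
    """Block-wise clustering with representative spill to disk.

    Blocks are taken in length-sorted order.  Each block's sequences are
    first compared against the representatives of previous blocks (read
    back from the spill file); the unassigned remainder is clustered
    within the block and its new representatives are appended to the
    spill file.  With ``block_size >= len(db)`` the result is identical to
    :func:`cluster`.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    params = params or ClusterParams()
    scoring = scoring or ScoringModel.blosum62()
    log = log if log is not None else ClusterLog()
    _check_unique_ids(db)
    ordered = seqio.sort_by_length(db)
    db_residues = sum(len(r) for r in db)

    tmp_ctx = None
    if workdir is None:
        tmp_ctx = tempfile.TemporaryDirectory(prefix="kclust_blocks_")
        workdir = tmp_ctx.name
    spill = Path(workdir) / "representatives_spill.fasta"
    spill.write_text("")

    clusters: list[Cluster] = []
    cluster_of_rep: dict[str, Cluster] = {}
    try:
        for start in range(0, len(ordered), block_size):
            block = ordered[start : start + block_size]
            remainder = block
            prev_reps = seqio.read_fasta(spill) if spill.stat().st_size else []
            if prev_reps:
                prev_table = IndexTable(params.spec6, scoring)
                prev_clusters: list[Cluster] = []
                for rep in prev_reps:
                    prev_table.add(encode(rep))
                    prev_clusters.append(cluster_of_rep[rep.id])
                remainder = []
                for record in block:
                    log.queries += 1
                    query = encode(record)
                    if not _try_assign(query, record, prev_table, prev_clusters,
                                       params, scoring, db_residues, log):
                        remainder.append(record)
            # cluster the remainder within the block
            table = IndexTable(params.spec6, scoring)
            block_clusters: list[Cluster] = []
            with open(spill, "a") as spill_out:
                for record in remainder:
                    if prev_reps:
                        pass  # query count already incremented above
                    else:
                        log.queries += 1
                    query = encode(record)
                    if not _try_assign(query, record, table, block_clusters,
                                       params, scoring, db_residues, log):
                        cl = Cluster(representative=record, creation_order=len(clusters))
                        clusters.append(cl)
                        cluster_of_rep[record.id] = cl
                        table.add(query)
                        block_clusters.append(cl)
                        spill_out.write(f">{record.header}\n{record.residues}\n")
    finally:
        if tmp_ctx is not None:
            tmp_ctx.cleanup()
    return Clustering(clusters, params, len(db), db_residues)


def _check_unique_ids(db: list[SequenceRecord]) -> None:
    seen: set[str] = set()
    for r in db:
        if r.id in seen:
            raise ValueError(f"duplicate sequence id {r.id!r}")
        seen.add(r.id)


# ---------------------------------------------------------------------------
# identity threshold convenience ("kclust 30" style)

_IDENTITY_ANCHOR = (30.0, DEFAULT_SCORE_PER_COLUMN)


@lru_cache(maxsize=8)
def _identity_calibration(seed: int) -> list[tuple[float, float]]:
    """Mean alignment score per column of synthetic homologous pairs at a
    grid of identities, shifted so 30% maps exactly to 1.12 half-bits."""
    from .synthetic import mutate_to_identity, random_sequence

    scoring = ScoringModel.blosum62()
    spec4 = KmerSpec.spaced_4mer()
    grid = [20.0, 30.0, 40.0, 50.0, 62.0, 75.0, 90.0, 100.0]
    points = []
    for g, ident in enumerate(grid):
        vals = []
        for rep in range(4):
            seq = random_sequence(180, seed=seed * 10007 + g * 101 + rep)
            mut = mutate_to_identity(seq, ident / 100.0, seed=seed * 7919 + g * 31 + rep)
            aln = kdp_align(encode(seq), encode(mut), spec4, scoring, db_size=10**6)
            if aln.pairs:
                vals.append(aln.score_per_column)
        points.append((ident, sum(vals) / len(vals)))
    # force the curve through the 30% anchor
    measured_30 = _interp(points, _IDENTITY_ANCHOR[0])
    shift = _IDENTITY_ANCHOR[1] - measured_30
    return [(x, y + shift) for x, y in points]


def _interp(points: list[tuple[float, float]], x: float) -> float:
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    if x <= xs[0]:
        return ys[0]
    if x >= xs[-1]:
        return ys[-1]
    for (x0, y0), (x1, y1) in zip(points, points[1:]):
        if x0 <= x <= x1:
            return y0 + (y1 - y0) * (x - x0) / (x1 - x0)
    raise AssertionError  # pragma: no cover


def identity_to_score_per_column(identity_pct: float, seed: int = 0) -> float:
    """Map a clustering identity threshold (percent) to a score-per-column
    threshold in half-bits.

    Anchored so 30% maps exactly to 1.12 half-bits per column; other
    identities are interpolated on a seeded synthetic-pair calibration
    curve.  Identity 0 means maximum sensitivity (no score-per-column
    criterion)."""
    if identity_pct <= 0:
        return -math.inf
    if identity_pct == _IDENTITY_ANCHOR[0]:
        return _IDENTITY_ANCHOR[1]
    return _interp(_identity_calibration(seed), identity_pct)
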