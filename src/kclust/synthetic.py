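"""Seeded generators for synthetic protein databases.

Three kinds of inputs are produced, all byte-deterministic for a fixed
seed: background sequences drawn i.i.d. from amino-acid background
frequencies; homologous families obtained by point-mutating a seed
sequence to controlled pairwise identity, with substitutions drawn from
the substitution-matrix-conditional distribution of the original residue
(so mutated homologs have realistic similar-k-mer statistics); and
artificial two-domain databases built by concatenating members of two
families, with sequences rejected when the longer domain exceeds a
maximum fraction (default 80%) of the total length.

Truth labels (family / architecture) are embedded in FASTA headers as
``|FAM=...`` / ``|ARCH=...`` suffix tags so that generated databases
round-trip through a single file.
"""

from __future__ import annotations

import re
from dataclasses import dataclass

import numpy as np

from .kmer_engine import ROBINSON_BACKGROUND, ScoringModel
from .seqio import AMINO_ACIDS, SequenceRecord

_LETTERS = np.frombuffer(AMINO_ACIDS.encode(), dtype=np.uint8)


def _codes_to_str(codes: np.ndarray) -> str:
    return _LETTERS[codes].tobytes().decode()


def random_sequence(
    length: int,
    background: np.ndarray | None = None,
    seed: int = 0,
    seq_id: str = "s0",
) -> SequenceRecord:
    """A sequence of i.i.d. background draws; deterministic per seed."""
    if length < 1:
        raise ValueError("length must be >= 1")
    if background is None:
        background = ROBINSON_BACKGROUND
    rng = np.random.default_rng(seed)
    codes = rng.choice(20, size=length, p=background)
    return SequenceRecord(id=seq_id, header=seq_id, residues=_codes_to_str(codes))


def _conditional_substitution(scoring: ScoringModel) -> np.ndarray:
    """P(y | x) proportional to f_y * 2**(S(x,y)/2), diagonal zeroed.

    This is the substitution-matrix pair-frequency conditional, i.e. the
    distribution of residues aligned to x in true homologs, restricted to
    actual substitutions."""
    S = scoring.matrix[:20, :20].astype(float)
    cond = scoring.background[None, :] * np.exp2(S / 2.0)
    np.fill_diagonal(cond, 0.0)
    cond /= cond.sum(axis=1, keepdims=True)
    return cond


def mutate_to_identity(
    seq: SequenceRecord,
    identity: float,
    seed: int = 0,
    scoring: ScoringModel | None = None,
    seq_id: str | None = None,
) -> SequenceRecord:
    """Substitute exactly ``round((1 - identity) * L)`` positions.

    Substituted residues are drawn from the matrix-conditional
    distribution of the original residue and never reproduce it, so the
    realized gapless identity equals the target to within 1/L.
    """
    if not 0 < identity <= 1:
        raise ValueError("identity must be in (0, 1]")
    scoring = scoring or ScoringModel.blosum62()
    L = len(seq.residues)
    n_sub = round((1.0 - identity) * L)
    rng = np.random.default_rng(seed)
    codes = np.frombuffer(seq.residues.encode(), dtype=np.uint8).copy()
    code_of = {ord(a): i for i, a in enumerate(AMINO_ACIDS)}
    positions = rng.choice(L, size=n_sub, replace=False)
    cond = _conditional_substitution(scoring)
    for p in positions:
        x = code_of[codes[p]]
        y = rng.choice(20, p=cond[x])
        codes[p] = _LETTERS[y]
    new_id = seq_id if seq_id is not None else seq.id + "_m"
    return SequenceRecord(id=new_id, header=new_id, residues=codes.tobytes().decode())


@dataclass(frozen=True)
class FamilySpec:
    """A homologous family: one seed sequence plus members at controlled
    identity to the seed."""

    family_id: str
    n_members: int
    seed_length: int
    identity_lo: float
    identity_hi: float
    seed: int = 0
    length_jitter: float = 0.1  # terminal truncation/extension, +-fraction

    def __post_init__(self):
        if not 0 < self.identity_lo <= self.identity_hi <= 1:
            raise ValueError("identity range must satisfy 0 < lo <= hi <= 1")


def make_family(spec: FamilySpec, scoring: ScoringModel | None = None) -> list[SequenceRecord]:
    """Generate a family; headers carry ``|FAM=<family_id>`` truth tags.

    The first record is the seed; each member's identity to the seed is
    uniform in [lo, hi], and member lengths vary by +-``length_jitter``
    via terminal truncation or background-composition extension.
    """
    scoring = scoring or ScoringModel.blosum62()
    rng = np.random.default_rng(spec.seed)
    seed_seq = random_sequence(
        spec.seed_length, scoring.background, seed=spec.seed * 2654435761 % (2**31),
        seq_id=f"{spec.family_id}_seed",
    )
    out = [_tag(seed_seq, fam=spec.family_id)]
    for m in range(1, spec.n_members):
        ident = rng.uniform(spec.identity_lo, spec.identity_hi)
        mut = mutate_to_identity(
            seed_seq, ident, seed=int(rng.integers(2**31)), scoring=scoring,
            seq_id=f"{spec.family_id}_{m}",
        )
        if spec.length_jitter > 0:
            mut = _jitter_length(mut, spec.length_jitter, rng, scoring)
        out.append(_tag(mut, fam=spec.family_id))
    return out


def _jitter_length(rec: SequenceRecord, jitter: float, rng, scoring: ScoringModel) -> SequenceRecord:
    L = len(rec.residues)
    delta = int(round(L * rng.uniform(-jitter, jitter)))
    residues = rec.residues
    if delta < 0:
        cut = -delta
        left = int(rng.integers(cut + 1))
        residues = residues[left : L - (cut - left)]
    elif delta > 0:
        ext = random_sequence(delta, scoring.background, seed=int(rng.integers(2**31))).residues
        split = int(rng.integers(delta + 1))
        residues = ext[:split] + residues + ext[split:]
    return SequenceRecord(id=rec.id, header=rec.header, residues=residues)


@dataclass(frozen=True)
class TwoDomainSpec:
    """Artificial two-domain database: pairs of distinct families glued
    end to end, rejecting sequences whose longer domain covers more than
    ``max_domain_fraction`` of the total length."""

    architectures: tuple[tuple[str, str], ...]
    n_per_architecture: int
    max_domain_fraction: float = 0.8
    seed: int = 0

    def __post_init__(self):
        for a, b in self.architectures:
            if a == b:
                raise ValueError("architectures must pair distinct families")


def make_two_domain_db(
    spec: TwoDomainSpec,
    families: dict[str, list[SequenceRecord]],
    max_retries: int = 200,
) -> list[SequenceRecord]:
    """Concatenate one member of each family per architecture; headers
    carry ``|ARCH=<famA>+<famB>`` truth tags."""
    for a, b in spec.architectures:
        for f in (a, b):
            if f not in families:
                raise ValueError(f"family {f!r} not provided")
    rng = np.random.default_rng(spec.seed)
    out = []
    for a, b in spec.architectures:
        arch = f"{a}+{b}"
        for i in range(spec.n_per_architecture):
            for _attempt in range(max_retries):
                ra = families[a][int(rng.integers(len(families[a])))]
                rb = families[b][int(rng.integers(len(families[b])))]
                total = len(ra.residues) + len(rb.residues)
                longer = max(len(ra.residues), len(rb.residues))
                if longer / total <= spec.max_domain_fraction:
                    break
            else:
                raise RuntimeError(
                    f"could not satisfy the domain-fraction rule for {arch}"
                )
            rec = SequenceRecord(
                id=f"{arch}_{i}",
                header=f"{arch}_{i}",
                residues=ra.residues + rb.residues,
            )
            out.append(_tag(rec, arch=arch))
    return out


_FAM_RE = re.compile(r"\|FAM=([^|\s]+)")
_ARCH_RE = re.compile(r"\|ARCH=([^|\s]+)")


def _tag(rec: SequenceRecord, fam: str | None = None, arch: str | None = None) -> SequenceRecord:
    # tags are whitespace-separated from the id so the id survives a
    # FASTA round trip unchanged
    header = rec.header
    if fam is not None:
        header += f" |FAM={fam}"
    if arch is not None:
        header += f" |ARCH={arch}"
    return SequenceRecord(id=rec.id, header=header, residues=rec.residues)


def truth_label(rec: SequenceRecord) -> str | None:
    """Family or architecture label parsed back from the header tag."""
    m = _ARCH_RE.search(rec.header)
    if m:
        return m.group(1)
    m = _FAM_RE.search(rec.header)
    if m:
        return m.group(1)
    return None


def labels_of(records: list[SequenceRecord]) -> dict[str, str]:
    out = {}
    for r in records:
        lab = truth_label(r)
        if lab is not None:
            out[r.id] = lab
    return out


@dataclass
class ClusteringReport:
    n_clusters: int
    n_corrupted: int
    corrupted_fraction: float
    wrong_per_corrupted: float


def score_partition(members_by_cluster: list[list[str]], labels: dict[str, str]) -> ClusteringReport:
    """Corrupted-cluster report for a partition given as id lists."""
    n_corrupted = 0
    wrong_counts = []
    for ids in members_by_cluster:
        try:
            labs = [labels[i] for i in ids]
        except KeyError as e:
            raise ValueError(f"missing truth label for sequence {e.args[0]!r}") from None
        distinct = set(labs)
        if len(distinct) > 1:
            n_corrupted += 1
            majority = max(distinct, key=labs.count)
            wrong_counts.append(sum(1 for l in labs if l != majority))
    n = len(members_by_cluster)
    return ClusteringReport(
        n_clusters=n,
        n_corrupted=n_corrupted,
        corrupted_fraction=n_corrupted / n if n else 0.0,
        wrong_per_corrupted=(sum(wrong_counts) / len(wrong_counts)) if wrong_counts else 0.0,
    )


def score_clustering(clustering, labels: dict[str, str]) -> ClusteringReport:
    """Corrupted-cluster report against truth labels.

    A cluster is corrupted when it contains at least two distinct truth
    labels; its wrong sequences are the members not carrying the
    cluster's majority label (ties broken toward fewer wrong sequences).
    """
    return score_partition([cl.member_ids() for cl in clustering.clusters], labels)
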