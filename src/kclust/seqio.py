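"""Sequence input/output and integer encoding.

Protein sequences are handled over a 21-letter alphabet: the 20 standard
amino acids in substitution-matrix row order (A R N D C Q E G H I L K M F
P S T W Y V, codes 0-19) plus a wildcard/unknown class (code 20).
Ambiguity codes (B, Z, J, U, O, X) and any other letter map to the
wildcard at encoding time; they are never rejected, because real sequence
databases contain them.
"""

from __future__ import annotations

import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, TYPE_CHECKING

import numpy as np
from Bio.SeqIO.FastaIO import SimpleFastaParser

if TYPE_CHECKING:  # pragma: no cover
    from .greedy_cluster import Clustering

#: The 20 standard amino acids in substitution-matrix row order.
AMINO_ACIDS = "ARNDCQEGHILKMFPSTWYV"

#: Code reserved for the wildcard/unknown residue class.
WILDCARD = 20

#: Alphabet size including the wildcard class.
ALPHABET_SIZE = 21

_CODE_OF = np.full(128, WILDCARD, dtype=np.int64)
for _i, _a in enumerate(AMINO_ACIDS):
    _CODE_OF[ord(_a)] = _i

_LETTER_OF = AMINO_ACIDS + "X"


class FastaParseError(ValueError):
    """Raised for malformed FASTA input."""


@dataclass
class SequenceRecord:
    """One FASTA entry.

    ``id`` is the first whitespace-delimited word of the header line,
    ``header`` the full description line (without '>'), ``residues`` the
    uppercased amino-acid string with '*' and gap characters removed.
    """

    id: str
    header: str
    residues: str

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class EncodedSequence:
    """A sequence mapped to integer codes in [0, 20]."""

    id: str
    codes: np.ndarray  # int64, values in [0, 20]

    @property
    def length(self) -> int:
        return int(self.codes.shape[0])

    def __len__(self) -> int:
        return self.length


def encode(record: SequenceRecord) -> EncodedSequence:
    """Map a record's residues to integer codes (non-standard -> wildcard)."""
    raw = np.frombuffer(record.residues.encode("ascii"), dtype=np.uint8)
    return EncodedSequence(id=record.id, codes=_CODE_OF[raw])


def decode_codes(codes: Iterable[int]) -> str:
    """Inverse of :func:`encode` up to the wildcard class (rendered 'X')."""
    return "".join(_LETTER_OF[c] for c in codes)


_STRIP = str.maketrans("", "", "*-. \t")


def read_fasta(path: str | os.PathLike) -> list[SequenceRecord]:
    """Read a FASTA file into a list of :class:`SequenceRecord`.

    Multi-line sequences are concatenated, lowercase letters uppercased and
    '*' / gap characters stripped.  Sequence data before the first header
    raises :class:`FastaParseError` naming the offending line; duplicate
    ids raise ``ValueError``.
    """
    path = Path(path)
    with open(path) as handle:
        # SimpleFastaParser silently skips leading junk; detect it here so
        # the error can carry a line number.  Later non-header lines always
        # belong to the preceding record, so one check suffices.
        for lineno, line in enumerate(handle, start=1):
            if not line.strip():
                continue
            if not line.startswith(">"):
                raise FastaParseError(
                    f"{path}: sequence data before first '>' header at line {lineno}"
                )
            break
        handle.seek(0)
        records = []
        seen: set[str] = set()
        for title, seq in SimpleFastaParser(handle):
            seq_id = title.split(None, 1)[0] if title.strip() else ""
            if not seq_id:
                raise FastaParseError(f"{path}: empty FASTA header")
            if seq_id in seen:
                raise ValueError(f"{path}: duplicate sequence id {seq_id!r}")
            seen.add(seq_id)
            records.append(
                SequenceRecord(
                    id=seq_id,
                    header=title,
                    residues=seq.translate(_STRIP).upper(),
                )
            )
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | os.PathLike, width: int = 60) -> None:
    """Write records as FASTA, wrapping sequence lines at ``width``."""
    with open(path, "w") as out:
        for rec in records:
            out.write(f">{rec.header}\n")
            for i in range(0, len(rec.residues), width):
                out.write(rec.residues[i : i + width] + "\n")


def sort_by_length(records: list[SequenceRecord]) -> list[SequenceRecord]:
    """Sort descending by length; ties keep input order (stable)."""
    return sorted(records, key=lambda r: -len(r.residues))


def write_clustering(
    clustering: "Clustering",
    directory: str | os.PathLike,
    per_cluster_fasta: bool = False,
) -> None:
    """Write clustering outputs into ``directory``.

    Produces ``clusters.tsv`` (representative_id <TAB> member_id, one line
    per member, the representative listed as its own member) and
    ``representatives.fasta``.  With ``per_cluster_fasta`` each cluster's
    members are additionally written to ``clusters/<n>.fasta``.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    with open(directory / "clusters.tsv", "w") as tsv:
        for cl in clustering.clusters:
            tsv.write(f"{cl.representative.id}\t{cl.representative.id}\n")
            for member, _aln in cl.members:
                tsv.write(f"{cl.representative.id}\t{member.id}\n")
    write_fasta(
        (cl.representative for cl in clustering.clusters),
        directory / "representatives.fasta",
    )
    if per_cluster_fasta:
        subdir = directory / "clusters"
        subdir.mkdir(exist_ok=True)
        for i, cl in enumerate(clustering.clusters):
            recs = [cl.representative] + [m for m, _ in cl.members]
            write_fasta(recs, subdir / f"{i}.fasta")
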